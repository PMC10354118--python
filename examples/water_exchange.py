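"""Aquaporin water permeability from an H₂O/D₂O exchange movie.

Generates a synthetic 50-fps exchange series for a dome-shaped cell with a
known intracellular decay time, then runs the full analysis: height map
from the MIR-OFF phase, Lambert–Beer contribution ratio, per-pixel decay
fits, surface/volume integrals and P_d.
"""

import numpy as np

from mipqpi.exchange import (
    HeightCalibration,
    cell_mask,
    fit_decay_map,
    fit_extracellular,
    height_from_phase,
    permeability,
    surface_and_volume,
)
from mipqpi.synth import GeneratorConfig, make_exchange_series, make_phantom_cell

cfg = GeneratorConfig(seed=42, shape=(128, 128))
phantom = make_phantom_cell(cfg)
series, truth = make_exchange_series(phantom, tau_map=420.0, noise=1.2, config=cfg)

t0, tau_ext = fit_extracellular(series, roi=(2, 2, 12, 12))
print(f"extracellular fit: exchange onset t0 = {t0:.0f} ms, tau_ext = {tau_ext:.0f} ms")

h = height_from_phase(phantom.phase, HeightCalibration(), pixel_size=cfg.pixel_size)
mask = cell_mask(h)
tau_map, diag = fit_decay_map(series, h, mask=mask)
tau_mean = float(np.nanmean(tau_map[mask]))
s, v = surface_and_volume(h, mask=mask)
p_d = permeability(tau_mean, s, v)

print(f"cell height map: peak {h.max():.1f} um over {mask.sum()} pixels "
      f"({diag['n_fit']} fitted)")
print(f"mean intracellular decay time tau = {tau_mean:.0f} ms (truth: 420 ms)")
print(f"surface S = {s:.0f} um^2, volume V = {v:.0f} um^3")
print(f"P_d = {p_d:.2e} cm/s")
print("-> the decay time alone depends on cell shape; P_d = 1/(tau S/V) "
      "is the membrane property.")
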