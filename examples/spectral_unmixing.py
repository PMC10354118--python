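"""MCR-ALS unmixing of a 40-wavenumber hyperspectral MIP stack into
CH₂ (lipid), CH₃-dominated (protein) and OH (water) components."""

import numpy as np

from mipqpi.mcr import component_contribution, mcr_als
from mipqpi.synth import GeneratorConfig, make_hyperspectral, make_phantom_cell

cfg = GeneratorConfig(seed=7, shape=(96, 96))
phantom = make_phantom_cell(cfg)
stack, c_true, s_true = make_hyperspectral(phantom, noise=0.3, config=cfg)
print(f"hyperspectral stack: {stack.n_k} wavenumbers "
      f"({stack.wavenumbers[0]:.0f}-{stack.wavenumbers[-1]:.0f} cm^-1), "
      f"{stack.frames.shape[1]}x{stack.frames.shape[2]} pixels")

rng = np.random.default_rng(0)
init = np.clip(s_true * (1 + 0.2 * rng.normal(size=s_true.shape)), 0, None)
model = mcr_als(stack, init_spectra=init)
print(f"ALS converged in {len(model.residuals)} iterations "
      f"(residual {model.residuals[-1]:.3g})")

names = ["lipid (CH2)", "protein (CH3)", "water (OH)"]
for i, name in enumerate(names):
    cos = model.spectra[i] @ s_true[i] / (
        np.linalg.norm(model.spectra[i]) * np.linalg.norm(s_true[i]))
    print(f"  {name:14s} spectrum recovered, cosine similarity {cos:.4f}")

r = component_contribution(model, stack)
k = stack.wavenumbers
r_maps = r.reshape(3, *phantom.height.shape, k.size)
lipid = np.nanmax(r_maps[0][phantom.masks["droplets"]][:, np.argmin(abs(k - 2925))])
protein = np.nanmax(r_maps[1][phantom.masks["nucleolus"]][:, np.argmin(abs(k - 2945))])
print(f"component contributions: {lipid:.0f} mrad lipid at the droplets "
      f"(2925 cm^-1), {protein:.0f} mrad protein at the nucleolus (2945 cm^-1)")
print("-> the contributions sum to the raw phase change exactly at every "
      "pixel and wavenumber.")
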