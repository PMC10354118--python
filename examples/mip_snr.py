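"""MIP image formation and SNR: ON−OFF differencing, water-background
subtraction, beam-profile correction."""

import numpy as np

from mipqpi.core import PhaseMap
from mipqpi.mip import (
    MIPFramePair,
    beam_profile_correct,
    evaluate_snr,
    mip_image,
    subtract_water_background,
)

rng = np.random.default_rng(0)
n, sigma_noise = 128, 1.6  # mrad frame noise

# synthetic scene: Gaussian MIR beam heating water, plus a lipid droplet
yy, xx = np.mgrid[0:n, 0:n]
beam = np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 45.0**2))
droplet = 100.0 * (np.hypot(yy - 40.0, xx - 80.0) < 4)

def noisy(img):
    return PhaseMap(img + rng.normal(0, sigma_noise, img.shape))

mip = mip_image(MIPFramePair(noisy(60.0 * beam + droplet), noisy(np.zeros((n, n)))))
water = mip_image(MIPFramePair(noisy(60.0 * beam), noisy(np.zeros((n, n)))))

raw_rep = evaluate_snr(mip, signal_pixel=(40, 80), noise_box=(90, 10))
sub = subtract_water_background(mip, water)
sub_rep = evaluate_snr(sub, signal_pixel=(40, 80), noise_box=(90, 10))
flat = beam_profile_correct(sub, water)

print(f"droplet pixel before subtraction: {raw_rep.signal:.0f} mrad "
      "(droplet + water background)")
print(f"noise box before subtraction: {raw_rep.noise:.1f} mrad "
      "(frame noise + the beam gradient across the box)")
print(f"after water-background subtraction: signal {sub_rep.signal:.0f} mrad, "
      f"noise {sub_rep.noise:.1f} mrad (sqrt(2) x the single-image frame noise), "
      f"SNR {sub_rep.snr:.0f}")
print(f"beam-corrected droplet amplitude: {np.nanmax(flat.values):.0f} mrad "
      "(flat response across the field)")
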