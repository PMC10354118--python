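"""Design rules for the MIR pulse: how thermal diffusion limits resolution.

Simulates a 500-nm water-like sphere heated by MIR pulses of different
durations and probed at different delays, and the cooling of the wide-field
heat load between pulses.
"""

from mipqpi.layered import decay_time, solve_layered_decay
from mipqpi.thermal import (
    cw_resolution_plateau,
    probe_delay_metrics,
    resolution_degradation,
)

R = 0.25  # sphere radius, µm

short = resolution_degradation(R, 0.01)
long_pulse = resolution_degradation(R, 0.1)
cw = cw_resolution_plateau(R)
print(f"e2-radius / object-radius, 10-ns pulse : {short:.2f}")
print(f"e2-radius / object-radius, 100-ns pulse: {long_pulse:.2f}")
print(f"e2-radius / object-radius, CW limit    : {cw:.2f}")
print("-> pulses of ~10 ns keep the image at the object's size; 100 ns "
      "already blurs it by ~1.3x and CW heating by ~4.8x.\n")

(ratio, frac), = probe_delay_metrics(R, [0.1])
print(f"probe 100 ns after a 10-ns pulse: radius ratio {ratio:.2f}, "
      f"remaining phase {100 * frac:.0f}%")
print("-> the probe must follow the pump within ~10 ns.\n")

t, y = solve_layered_decay(t_end=1000.0)
print(f"10-um water layer between CaF2 windows: 1/e decay at "
      f"{decay_time(t, y):.0f} us, residual at 1 ms = {100 * y[-1]:.2f}%")
print("-> a 1-kHz repetition rate leaves no thermal pile-up.")
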