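# mipqpi

Simulation and analysis toolkit for **wide-field mid-infrared photothermal
quantitative phase imaging (MIP-QPI)** — label-free vibrational imaging of
live cells at video rate.

In MIP-QPI, a nanosecond mid-infrared (MIR) pulse excites molecular
vibrations (CH₂/CH₃ stretches of lipids and proteins, the OH band of
water); the absorbed energy heats the sample locally, and the thermo-optic
index change is read out as an optical phase shift by a visible-light
off-axis holographic microscope:

    Δθ(x, y, t) ≈ (2π/λ) (dn/dT) ∫ ΔT(x, y, z, t) dz.

The package implements, as tested library code on synthetic inputs:

- **`mipqpi.thermal` / `mipqpi.layered`** — finite-volume heat-conduction
  solvers (spherical and layered-axial) with Abel projection to phase
  images, yielding the system design rules: how pulse duration, probe
  delay and repetition rate trade off against thermal blur and pile-up.
- **`mipqpi.holography`** — off-axis hologram synthesis, Fourier-sideband
  phase reconstruction, and the shot-noise phase budget
  σ = 2√([N + σ_s²]·A_ap / (v²N²A_s)) with closed-form visibility
  inversion.
- **`mipqpi.mip`** — MIP image formation (MIR-ON − MIR-OFF), water
  background subtraction, beam-profile correction, SNR reports.
- **`mipqpi.exchange`** — H₂O/D₂O exchange kinetics: biexponential decay
  with the Lambert–Beer contribution ratio A(h), per-pixel decay-time
  fits, surface/volume integrals and the diffusional water permeability
  P_d = 1/(τ·S/V) of the cell membrane (aquaporin activity).
- **`mipqpi.mcr`** — hyperspectral stack normalization and MCR-ALS
  unmixing (alternating exact NNLS) into lipid / protein / water
  component maps and spectra with exact contribution bookkeeping.
- **`mipqpi.synth`** — ground-truth generators (phantom cell, holograms,
  exchange movies, hyperspectral stacks) behind every round-trip test.
- **`mipqpi.io`** — TIFF/HDF5 stacks, CSV curves, validated YAML configs,
  provenance metadata.

## Worked example

`examples/` holds one narrative script per capability. For instance:

```sh
$ python examples/thermal_design.py
e2-radius / object-radius, 10-ns pulse : 1.04
e2-radius / object-radius, 100-ns pulse: 1.31
e2-radius / object-radius, CW limit    : 4.82
-> pulses of ~10 ns keep the image at the object's size; 100 ns already
   blurs it by ~1.3x and CW heating by ~4.8x.

probe 100 ns after a 10-ns pulse: radius ratio 1.69, remaining phase 48%
-> the probe must follow the pump within ~10 ns.

10-um water layer between CaF2 windows: 1/e decay at 54 us, residual at 1 ms = 0.00%
-> a 1-kHz repetition rate leaves no thermal pile-up.
```

The first block simulates a 500-nm water-like sphere heated at constant
power and measures how much thermal diffusion widens its phase image — the
case for ≤10-ns MIR pulses.  The last line simulates one MIR shot heating
the 10-µm water film between CaF₂ windows and shows the heat is gone well
before the next 1-kHz pulse.

```sh
$ python examples/water_exchange.py
extracellular fit: exchange onset t0 = 99 ms, tau_ext = 82 ms
cell height map: peak 5.4 um over 5816 pixels (5816 fitted)
mean intracellular decay time tau = 422 ms (truth: 420 ms)
surface S = 1185 um^2, volume V = 2964 um^3
P_d = 5.93e-04 cm/s
```

Here a synthetic 50-fps H₂O→D₂O exchange movie with a known intracellular
decay time of 420 ms is pushed through the full analysis; the recovered
τ = 422 ms and the membrane permeability P_d ≈ 6×10⁻⁴ cm/s (the
shape-independent quantity) come back within a few percent of the
generator's ground truth.

See also `examples/noise_budget.py` (phase-noise model vs Monte-Carlo
holograms), `examples/mip_snr.py` (image formation and SNR) and
`examples/spectral_unmixing.py` (MCR-ALS on a 40-wavenumber stack).

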