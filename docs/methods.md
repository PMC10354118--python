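# Methods

`mipqpi` models the computational chain of a wide-field mid-infrared
photothermal (MIP) quantitative-phase microscope: a nanosecond MIR pulse is
absorbed by molecular vibrations, the deposited heat changes the refractive
index through the thermo-optic effect, and a visible probe reads the
resulting optical phase delay

Δθ(x, y, t) ≈ (2π/λ) (dn/dT) ∫ ΔT(x, y, z, t) dz.

Everything downstream — spatial resolution, signal decay, noise floor,
kinetic fits, spectral unmixing — follows from this forward model.  All
phase images in the package carry mrad; lengths are µm, times µs (thermal)
or ms (kinetics).

## Thermal conduction

**Model.** ∂ΔT/∂t = ν∇²ΔT + q with pure conduction: no convection,
radiation, or temperature-dependent properties.  Two geometries:

1. *Spherically symmetric* — a uniformly heated sphere (an organelle-sized
   absorber) in water.  Material constants: ν = 0.146 µm² µs⁻¹,
   K = 0.618 W m⁻¹ K⁻¹ for water; the absorber is thermally water-like, as
   intracellular heat sources are ~80% water.
2. *Layered axial* — a 10-µm water film between CaF₂ windows
   (ν = 2.92 µm² µs⁻¹, K = 9.71 W m⁻¹ K⁻¹), heated impulsively with a
   Lambert–Beer axial profile (1/e depth 16 µm, interpreted as an
   attenuation length, not a hard cutoff) and a Gaussian lateral spot
   (FWHM 91 µm).

**Discretization.** Explicit forward-Euler on a conservative finite-volume
grid (spherical shells, resp. 1-D cells), time step
0.4 × Δx²/(2·d·ν_max) for dimensionality d.  The conservative form makes
total thermal energy exact to round-off under adiabatic boundaries (tested
to 0.1%), and the r = 0 singularity disappears into the zero-flux center
face.  Solutions are verified against the Gaussian Green's-function kernel
(σ² = σ₀² + 2νt, ≤1% for σ₀ ≥ 8 grid steps) and, for the diffusing sphere,
against the exact erf-form solution.

**Projection.** Phase images of spherical fields use the Abel projection,
evaluated as a direct line integral along z with the field interpolated at
r = √(x² + z²) — this avoids the 1/√(r² − x²) kernel singularity entirely.
The microscope PSF is deliberately not applied; image metrics quantify
thermal blur only.  The sign convention reports |Δθ| (water's dn/dT is
negative; the imaging convention plots positive phase change).

**Design metrics.**

- *Resolution degradation*: e⁻² radius of the projected phase image over
  the true sphere radius, probed at pulse end.  For a 0.25-µm sphere this
  is 0.99 at vanishing duration (pure chord-projection geometry,
  R√(1 − e⁻⁴)) and 1.31 at 100 ns.
- *CW limit*: under continuous constant-power heating the projected image
  has no finite e⁻² radius — the quasi-steady 1/r far field projects to a
  logarithm that widens with the diffusion front (~√t; we measured the
  projected ratio passing 9.7 at 32 µs with no plateau).  The
  *temperature field*, however, reaches a steady state whose e⁻² radius is
  analytically (2/3)e² ≈ 4.93 sphere radii in an unbounded bath.
  `cw_resolution_plateau` therefore solves the steady conduction problem
  (banded linear system on the same finite-volume grid, heat-sink boundary
  at 200 radii by default) and reports the 3-D thermal-spread ratio, ≈4.8
  with the default bath distance.
- *Probe delay*: after a 10-ns pulse, 100 ns of free diffusion leaves 48%
  of the center phase and widens the image 1.69× — the latter agrees with
  the exact Green's-function oracle to three digits.  (Reported plots of
  this quantity read ~1.9 at the same delay; no variant of the stated
  model — 3-D temperature radius, Gaussian fits, alternative
  normalizations — reproduces that number, so the package reports its own
  computed value.)
- *Saturation time*: defined on the center temperature of the sphere
  (time to reach 1 − 1/e of the steady value qR²/2ν).  This is exactly
  self-similar in νt/R², giving the t_sat ∝ R² design rule; the projected
  center *phase* has no crisp saturation point (logarithmic growth) and is
  exposed as `saturation_curve` for inspection instead.

**Layered decay and the repetition rate.**  The decay of the z-integrated
water-layer temperature at the lateral spot center sets how fast one MIR
shot's heat clears before the next.  Two substrate models are available:

- `"sink"` (default): the windows pin the interfaces at ΔT = 0.  This
  infinite-effusivity idealization of the ~16×-more-conductive CaF₂ gives
  a 1/e time of ≈54 µs for the 10-µm film — the regime in which the
  reported design simulations of this geometry land (≈57 µs).  Verified
  against the exact Dirichlet-slab Fourier series to 1%.
- `"conducting"`: the full finite-volume solve across the stack with
  harmonic-mean face conductivities (the exact treatment of flux
  continuity for piecewise-constant media).  Because CaF₂'s effusivity is
  only ≈3.5× water's, the interfaces stay warm and the decay takes ≈95 µs.
  Verified against an independent BDF method-of-lines integration and
  against the homogeneous-medium analytic limit.

The truth lies between the models (a measured counterpart of this decay is
74 µs); both are kept and documented rather than hiding the discrepancy.
Lateral diffusion of the 91-µm spot is applied as the exact analytic
Gaussian factor σ²/(σ² + 2νt) on the center amplitude (~1% at 50 µs);
a full 2-D (r, z) solve is unnecessary at these time scales.

## Phase-noise budget and holography

The temporal phase noise of off-axis QPI, evaluated as the STD of
frame-difference phase images, is

σ_phase = 2 √([N_e + σ_sensor²] A_aperture / (v² N_e² A_sensor)),

derived from: white detection noise of variance N_e + σ_sensor² per pixel
spreads uniformly over the Fourier plane; the sideband crop keeps the
fraction A_aperture/A_sensor of it; the phase error of a complex field of
magnitude v·N_e/2 is the quadrature noise over the magnitude (one √2); and
frame differencing doubles the variance (the second √2).  The Monte-Carlo
pipeline (Poisson + Gaussian hologram synthesis → FFT → hard circular
sideband crop → arg) reproduces this closed form within 5% across
v ∈ {0.5, 0.8, 1}, N_e ∈ {10³, 10⁴, 10⁵}, σ_sensor ∈ {0, 572 e⁻}, provided
the per-pixel phase error stays in the linear range of arg() — the
acceptance test sizes its aperture accordingly; at very low SNR the
estimator variance exceeds the linearized model, which is physics, not a
solver defect.

Aperture pixel counts use the nearest-integer π/4·D² convention
(245 px → 47,144; 201 px → 31,731).  Fringe visibility is not directly
given; it is recovered by closed-form inversion of the noise model at a
measured operating point (0.9 mrad at N_e = 3.6×10⁵ with σ_sensor = 572 e⁻
on a 1440² sensor → v ≈ 0.77), which then predicts the 0.39-mrad shot
limit at N_e = 10⁶.  Quantization uses round-half-even at
full_well/((2^bits − 1)·gain) electrons per digital number; clipping at
the code limits warns rather than fails.

## MIP image pipeline

MIP image = ON − OFF phase difference; water-background subtraction
removes the beam-shaped water response at the cost of √2 noise;
beam-profile correction divides by the max-normalized water image with
pixels below 5% of the beam maximum masked as NaN (configurable) to avoid
skirt blow-up.  SNR is signal at a pixel over the spatial STD of a
20×20-pixel box.  Boxes are 0-based, origin + size, half-open.  No frame
registration or drift correction is attempted (the common-path design is
assumed stable).

## H₂O/D₂O exchange and water permeability

Per pixel the normalized decay is
I(t) = A(h)·exp(−(t−t₀)/τ_ext) + (1−A(h))·exp(−(t−t₀)/τ) with
A(h) = (e^(−h/D_z) − e^(−L/D_z))/(1 − e^(−L/D_z)), D_z = 6.73 µm at
3014 cm⁻¹, L = 20 µm.  t₀ and τ_ext come from a single-exponential fit of
a cell-free region (A ≡ 1); per-pixel fits then solve for τ only, bounded
to (10, 5000] ms, with the analytic Jacobian, restricted to t ≥ 120 ms to
sit past the liquid-exchange agitation artifact; pixels with A > 0.995
(no cell above them) are flagged unidentifiable and excluded.

Cell height comes from the MIR-OFF phase via h = LP(φ)·λ/(2πΔn) with
Δn = 0.0323 and a Gaussian low-pass of σ = 1.5 µm (≈3 pixels).  The σ was
chosen by a ground-truth fidelity study on the synthetic dome cell: σ of
5 µm biases S/V by +28% (mask dilation and slope flattening) and the
fitted τ by −9% through the A(h) mismatch, while 1.5 µm keeps both within
~2% and still suppresses per-pixel phase noise.  Heights are clipped to
[0, 20] µm (the capillary depth); the cell mask is h > 0.5 µm.

S = Σ√(1 + h_x² + h_y²)ΔxΔy and V = Σh ΔxΔy use central differences at
Δx = Δy = 0.44 µm.  The estimator converges slowly (O(√Δx)) for bodies
with vertical rims — a hemisphere needs Δx ≈ R/200 for 3% — but actual
adherent-cell shapes have bounded slopes where convergence is fast.
Finally P_d = 1/(τ·S/V), reported in cm s⁻¹ (×10⁻⁴ from µm s⁻¹); with the
reported cell geometry (τ = 420 ms, S = 1404 µm², V = 3779 µm³) this is
6.4×10⁻⁴ cm s⁻¹.  The full synthetic pipeline (generate → height → A →
fit → S, V → P_d) recovers a known permeability within ~3% at 2% frame
noise; the test budget allows 10%.

## Hyperspectral MCR-ALS

H(x, k) = Σᵢ Cᵢ(x)Sᵢ(k) with C, S ≥ 0, solved by alternating exact
non-negative least squares.  For ≤8 components the NNLS is solved by
vectorized support-set enumeration (the optimum is the feasible subset
solution with minimal residual), bit-identical to Lawson–Hanson but
~10³× faster over many pixels; the residual is non-increasing by
construction.  Stopping: relative residual change < 1e-8 or 500
iterations.  Component identity follows the initialization (ROI-mean
spectra: water-background-subtracted for intracellular ROIs, raw for the
extracellular one); scale/permutation ambiguity is handled only in tests.
Contributions Rᵢ = CᵢSᵢ/ΣⱼCⱼSⱼ × Δ∅ conserve the raw stack exactly where
the model is nonzero.  Normalization divides each wavenumber's frame by
the max-normalized water image and rescales by E(k_ref)/E(k).

## Synthetic data

Generators return ground truth alongside data; one integer seed fans out
through `SeedSequence.spawn`.  Defaults describe the imaging regime the
analysis targets: 256×256 px at 0.44 µm (a ~110-µm field), a dome cell of
21-µm footprint radius and 5.5-µm peak (S/V ≈ 0.39 µm⁻¹, matching the
measured-cell scale), 50-fps exchange series with t₀ = 99 ms,
τ_ext = 82 ms, τ = 420 ms, 1.6-mrad frame noise, lipid/protein/water
spectra as Gaussian bands (CH₂ 2854+2925 cm⁻¹; CH₃-dominated 2945 cm⁻¹;
OH broad at 3400 cm⁻¹, rising through the 2800–3250 window; widths at or
above the ~10 cm⁻¹ source linewidth), scaled to 40 mrad lipid at the
droplets and 14 mrad protein at the nucleolus.

What the generators deliberately omit: optical diffraction and PSF,
speckle, aberrations, halo artifacts, stage drift, photobleaching-free
but otherwise live-cell texture, and the water-dominated spectral
distortion discussed for real hyperspectral stacks.  Passing round-trip
tests therefore demonstrates correctness of the estimators under the
stated statistical model, not robustness to every instrument artifact.

## Numerical choices and limitations

- Test problem sizes (128² images, 300-µs thermal windows, 24-frame
  Monte-Carlo stacks) are the package's default verification scale; all
  solvers accept finer grids and the grid-refinement tests pin the
  discretization error below 3% at these settings.
- Degenerate inputs fail loudly: unstable time steps report the stability
  bound, non-decaying exchange traces and monotone profiles are rejected,
  zero-noise SNR boxes warn and report infinity.
- The layered-decay substrate question (ideal sink vs finite effusivity)
  and the CW-limit definition (steady-state 3-D spread) are genuinely open
  modeling choices; both alternatives are implemented, and the defaults
  are the variants consistent with the reported design numbers.
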