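"""Off-axis hologram synthesis, Fourier-sideband phase reconstruction, and
the shot-noise phase budget.

The temporal phase noise of an off-axis QPI system, evaluated as the
standard deviation of frame-difference phase images, follows

    σ_phase = 2 √( [N_e + σ_sensor²] · A_aperture / (v² N_e² A_sensor) ),

with N_e the mean electrons per pixel in the hologram, σ_sensor the read
noise in electrons, v the fringe visibility, A_sensor the total pixel count
and A_aperture the number of Fourier-plane pixels retained by the circular
sideband crop.  The factor 2 is √2 (quadrature noise → phase at the working
point) × √2 (difference of two frames); cropping A_aperture of A_sensor
frequency pixels keeps only that fraction of the white noise power
(spatial-averaging effect).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import PhaseMap

__all__ = [
    "SensorModel",
    "OffAxisConfig",
    "NoiseBudget",
    "SENSOR_2M",
    "SENSOR_10K",
    "aperture_pixels",
    "predict_phase_noise",
    "infer_visibility",
    "electrons_from_counts",
    "synthesize_hologram",
    "reconstruct_phase",
    "measure_temporal_noise",
    "sideband_mask",
]


@dataclass(frozen=True)
class SensorModel:
    """Image-sensor parameters relevant to the electron budget."""

    label: str
    full_well: float           # e⁻ per pixel
    bit_depth: int
    gain: float                # digital-scale factor in the DN→e⁻ conversion
    read_noise: float          # σ_sensor, e⁻
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.full_well <= 0:
            raise ValueError("full_well must be positive")
        if self.read_noise < 0:
            raise ValueError("read noise cannot be negative")

    @property
    def n_pixels(self) -> int:
        """A_sensor: total pixel count of a frame."""
        return int(self.frame_shape[0] * self.frame_shape[1])

    @property
    def electrons_per_count(self) -> float:
        """e⁻ per digital number: full_well / ((2^bits − 1) · gain)."""
        return self.full_well / ((2**self.bit_depth - 1) * self.gain)


#: High-full-well sensor used for the main demonstrations.
SENSOR_2M = SensorModel("2M", full_well=2e6, bit_depth=11, gain=1.73,
                        read_noise=572.0, frame_shape=(1440, 1440))
#: Conventional CMOS sensor used for comparison.
SENSOR_10K = SensorModel("10k", full_well=1e4, bit_depth=16, gain=1.0,
                         read_noise=0.0, frame_shape=(1023, 1023))


def aperture_pixels(diameter: float) -> int:
    """Number of Fourier-plane pixels in a circular crop of the given
    diameter, by the π/4·D² convention (nearest integer): 245 px → 47,144."""
    return int(round(math.pi / 4.0 * diameter**2))


@dataclass(frozen=True)
class OffAxisConfig:
    """Off-axis geometry: carrier frequency (cycles/pixel, (fy, fx)),
    sideband crop diameter in frequency pixels, and fringe visibility."""

    carrier: tuple[float, float]
    aperture_diameter: float
    visibility: float = 1.0
    frame_shape: tuple[int, int] = (1440, 1440)

    def __post_init__(self) -> None:
        if not 0.0 < self.visibility <= 1.0:
            raise ValueError("visibility must be in (0, 1]")
        fy, fx = self.carrier
        ny, nx = self.frame_shape
        carrier_pix = math.hypot(fy * ny, fx * nx)
        if carrier_pix <= self.aperture_diameter / 2.0:
            raise ValueError("carrier frequency inside the aperture: sideband not separable")

    @property
    def aperture_area(self) -> int:
        return aperture_pixels(self.aperture_diameter)


@dataclass(frozen=True)
class NoiseBudget:
    """Predicted phase-noise decomposition at one operating point (mrad)."""

    n_electron: float
    sigma_phase: float
    shot_only: float

    def __post_init__(self) -> None:
        if self.sigma_phase < self.shot_only:
            raise ValueError("total noise cannot be below the shot-noise floor")


def predict_phase_noise(
    n_electron: float,
    sensor: SensorModel,
    config: OffAxisConfig,
    aperture_area: int | None = None,
    sensor_area: int | None = None,
    read_noise: float | None = None,
) -> float:
    """Temporal phase noise in mrad for a mean electron count per pixel.

    With zero read noise this reduces to the shot-noise line
    σ = 2 √(A_ap / (v² N A_s)) ∝ 1/√N.
    """
    if n_electron <= 0:
        raise ValueError("n_electron must be positive")
    v = config.visibility
    a_ap = config.aperture_area if aperture_area is None else aperture_area
    a_s = sensor.n_pixels if sensor_area is None else sensor_area
    sig = sensor.read_noise if read_noise is None else read_noise
    rad = 2.0 * math.sqrt((n_electron + sig**2) * a_ap / (v**2 * n_electron**2 * a_s))
    return rad * 1e3


def noise_budget(n_electron: float, sensor: SensorModel, config: OffAxisConfig) -> NoiseBudget:
    """Total and shot-only phase noise at one operating point."""
    total = predict_phase_noise(n_electron, sensor, config)
    shot = predict_phase_noise(n_electron, sensor, config, read_noise=0.0)
    return NoiseBudget(n_electron=n_electron, sigma_phase=total, shot_only=shot)


def infer_visibility(
    sigma_phase_mrad: float,
    n_electron: float,
    sensor: SensorModel,
    aperture_area: int | None = None,
) -> float:
    """Fringe visibility implied by a measured temporal phase noise.

    Closed-form inversion of the noise model:
    v = (2/σ) √((N + σ_sensor²) A_ap / (N² A_s)).  Rejects inputs implying
    v > 1 (below the physical noise floor at unit visibility).
    """
    if sigma_phase_mrad <= 0 or n_electron <= 0:
        raise ValueError("noise and electron count must be positive")
    a_ap = aperture_area if aperture_area is not None else aperture_pixels(245)
    sigma_rad = sigma_phase_mrad * 1e-3
    v = (2.0 / sigma_rad) * math.sqrt(
        (n_electron + sensor.read_noise**2) * a_ap / (n_electron**2 * sensor.n_pixels)
    )
    if v > 1.0:
        raise ValueError(
            f"measured noise {sigma_phase_mrad} mrad is below the v = 1 floor "
            f"({v:.3f} would be required); inputs inconsistent"
        )
    return v


def electrons_from_counts(value: float | np.ndarray, sensor: SensorModel) -> float | np.ndarray:
    """Mean electrons per pixel from a sensor digital output value.

    N_e = value × full_well / ((2^bits − 1) · gain).  Negative values are
    rejected; values at or above the maximum code trigger a saturation
    warning.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("digital values cannot be negative")
    max_code = 2**sensor.bit_depth - 1
    if np.any(arr >= max_code):
        warnings.warn("digital value at full scale: sensor likely saturated", stacklevel=2)
    out = arr * sensor.electrons_per_count
    return float(out) if np.isscalar(value) else out


def _carrier_phase(config: OffAxisConfig, shape: tuple[int, int]) -> np.ndarray:
    fy, fx = config.carrier
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return 2.0 * math.pi * (fy * yy + fx * xx)


def synthesize_hologram(
    phase: PhaseMap | np.ndarray,
    config: OffAxisConfig,
    n_electron: float,
    sensor: SensorModel,
    rng: np.random.Generator | int | None = None,
    quantize: bool = True,
    shot_noise: bool = True,
) -> np.ndarray:
    """Forward model of an off-axis hologram in electrons (or digital counts).

    I(x) = N_e [1 + v cos(2π k·x + φ(x))], with Poisson shot noise, Gaussian
    read noise, and (optionally) round-half-even quantization at the
    sensor's e⁻/DN conversion with clipping at the code limits.  ``phase``
    is in mrad if a :class:`PhaseMap`, radians if a bare array.
    Deterministic under a fixed ``rng`` seed; ``shot_noise=False`` returns
    the noise-free interference pattern (read noise still applies if set).
    """
    if isinstance(phase, PhaseMap):
        phi = phase.values * 1e-3
    else:
        phi = np.asarray(phase, dtype=float)
    rng = np.random.default_rng(rng)
    carrier = _carrier_phase(config, phi.shape)
    ideal = n_electron * (1.0 + config.visibility * np.cos(carrier + phi))
    if n_electron * (1.0 + config.visibility) > sensor.full_well:
        warnings.warn("hologram mean exceeds full well: clipping will occur", stacklevel=2)
        ideal = np.clip(ideal, 0.0, sensor.full_well)
    noisy = rng.poisson(ideal).astype(float) if shot_noise else ideal.copy()
    if sensor.read_noise > 0:
        noisy += rng.normal(0.0, sensor.read_noise, size=noisy.shape)
    if not quantize:
        return noisy
    max_code = 2**sensor.bit_depth - 1
    counts = np.rint(noisy / sensor.electrons_per_count)  # round-half-even
    return np.clip(counts, 0, max_code).astype(np.uint16 if sensor.bit_depth <= 16 else np.uint32)


def sideband_mask(shape: tuple[int, int], config: OffAxisConfig) -> tuple[np.ndarray, tuple[int, int]]:
    ny, nx = shape
    fy, fx = config.carrier
    ky0 = int(round(fy * ny))
    kx0 = int(round(fx * nx))
    ky = np.arange(ny)
    kx = np.arange(nx)
    # periodic frequency distance to the carrier bin
    dy = np.minimum(np.abs(ky - ky0 % ny), ny - np.abs(ky - ky0 % ny))
    dx = np.minimum(np.abs(kx - kx0 % nx), nx - np.abs(kx - kx0 % nx))
    dist2 = dy[:, None] ** 2 + dx[None, :] ** 2
    mask = dist2 <= (config.aperture_diameter / 2.0) ** 2
    return mask, (ky0, kx0)


def reconstruct_phase(
    hologram: np.ndarray,
    config: OffAxisConfig,
    sensor: SensorModel | None = None,
    pixel_size: float = 0.44,
) -> PhaseMap:
    """Recover the phase image from an off-axis hologram.

    FFT → hard circular crop of ``aperture_diameter`` around the carrier →
    shift the carrier to zero frequency → inverse FFT → argument.  Output
    is the principal-value phase (no global unwrapping), in mrad.  Raises
    if the spectral peak is not found near the configured carrier.
    """
    holo = np.asarray(hologram, dtype=float)
    spec = np.fft.fft2(holo)
    mask, (ky0, kx0) = sideband_mask(holo.shape, config)
    # sanity: the strongest non-DC component must sit in one of the two
    # (conjugate-symmetric) sidebands around ±carrier
    ny, nx = holo.shape
    radius = config.aperture_diameter / 2.0
    ky = np.minimum(np.arange(ny), ny - np.arange(ny))
    kx = np.minimum(np.arange(nx), nx - np.arange(nx))
    dc = (ky[:, None] ** 2 + kx[None, :] ** 2) <= radius**2
    search = np.abs(spec) * ~dc
    peak = np.unravel_index(np.argmax(search), spec.shape)

    def _dist(py, px, cy, cx):
        dy = min((py - cy) % ny, (cy - py) % ny)
        dx = min((px - cx) % nx, (cx - px) % nx)
        return math.hypot(dy, dx)

    if min(_dist(*peak, ky0, kx0), _dist(*peak, -ky0, -kx0)) > radius:
        raise ValueError("no spectral peak near the configured carrier frequency")
    sideband = np.roll(spec * mask, (-ky0, -kx0), axis=(0, 1))
    field = np.fft.ifft2(sideband)
    return PhaseMap(values=np.angle(field) * 1e3, pixel_size=pixel_size)


def detect_carrier(hologram: np.ndarray, min_frequency: float = 0.05) -> tuple[float, float]:
    """Convenience spectral-peak carrier detection (cycles/pixel), ignoring
    frequencies below ``min_frequency`` from DC."""
    holo = np.asarray(hologram, dtype=float)
    ny, nx = holo.shape
    spec = np.abs(np.fft.fft2(holo - holo.mean()))
    fy = np.fft.fftfreq(ny)
    fx = np.fft.fftfreq(nx)
    rr = np.hypot(fy[:, None], fx[None, :])
    spec[rr < min_frequency] = 0.0
    spec[fy < 0, :] = 0.0  # keep the +fy half-plane representative
    ky, kx = np.unravel_index(np.argmax(spec), spec.shape)
    return float(fy[ky]), float(fx[kx])


def measure_temporal_noise(
    phase_stack: np.ndarray,
    roi: tuple[int, int, int, int] = (0, 0, 80, 80),
    estimator: str = "std",
) -> float:
    """Temporal phase noise (mrad) of a phase-image stack.

    Differences of adjacent frames are formed, the per-pixel temporal STD
    over those difference images is computed, and the result is averaged
    over an ``roi`` (y0, x0, height, width).  For i.i.d. frames of noise σ
    this returns √2 σ.  ``estimator="rms"`` averages the per-pixel variances
    before the square root (bias-free for small stacks).
    """
    stack = np.asarray(phase_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("need a stack of at least 3 frames")
    y0, x0, h, w = roi
    if y0 < 0 or x0 < 0 or y0 + h > stack.shape[1] or x0 + w > stack.shape[2]:
        raise ValueError("roi outside the image")
    diffs = stack[1:] - stack[:-1]
    region = diffs[:, y0 : y0 + h, x0 : x0 + w]
    if estimator == "std":
        per_pixel = region.std(axis=0, ddof=1)
        return float(per_pixel.mean())
    if estimator == "rms":
        per_pixel_var = region.var(axis=0, ddof=1)
        return float(math.sqrt(per_pixel_var.mean()))
    raise ValueError("estimator must be 'std' or 'rms'")
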