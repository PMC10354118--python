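"""H₂O/D₂O exchange analysis: from a time series of MIP images at the OH/OD
wavenumber to the diffusional membrane water permeability P_d.

When the extracellular H₂O buffer is replaced by D₂O, the MIP signal at an
H₂O-specific wavenumber decays.  Each pixel mixes two decays — fast
extracellular exchange (time constant τ_ext) and slow transmembrane export
of intracellular H₂O (τ) — weighted by the Lambert–Beer contribution ratio
A(h) of the water column above a cell of height h in a capillary of depth L:

    I(t) = A(h) exp(−(t−t₀)/τ_ext) + (1 − A(h)) exp(−(t−t₀)/τ),

    A(h) = (exp(−h/D_z) − exp(−L/D_z)) / (1 − exp(−L/D_z)),

with D_z the MIR attenuation depth (6.73 µm at 3014 cm⁻¹) and L = 20 µm.
Cell height comes from the MIR-OFF phase image via the intra/extracellular
refractive-index difference Δn = 0.0323; surface area S and volume V follow
from the height map, and

    P_d = 1 / (τ · (S/V))        (converted to cm s⁻¹).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "ExchangeSeries",
    "HeightCalibration",
    "DecayModel",
    "PermeabilityResult",
    "height_from_phase",
    "contribution_ratio",
    "fit_extracellular",
    "fit_decay_map",
    "surface_and_volume",
    "permeability",
    "cell_mask",
]


@dataclass
class ExchangeSeries:
    """Time-stamped MIP frame stack (mrad) recorded during the exchange.

    ``timestamps`` in ms must be strictly increasing and uniformly spaced
    within 1% (50 fps → 20-ms spacing).
    """

    timestamps: np.ndarray
    frames: np.ndarray
    wavenumber: float = 3014.0  # cm⁻¹

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape[0] != self.timestamps.size:
            raise ValueError("one timestamp per frame required")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if dt.size and (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise ValueError("timestamps must be uniformly spaced within 1%")


@dataclass(frozen=True)
class HeightCalibration:
    """Phase → height conversion: h = LP(φ) λ / (2π Δn)."""

    delta_n: float = 0.0323
    wavelength: float = 0.532      # µm
    lowpass_sigma: float = 1.5     # µm; Gaussian blur suppressing pixel noise
    max_height: float = 20.0       # µm, capillary depth

    def __post_init__(self) -> None:
        if self.delta_n <= 0:
            raise ValueError("delta_n must be positive")


@dataclass
class DecayModel:
    """Fixed parameters of the biexponential exchange model."""

    t0: float = 99.0          # ms, exchange onset
    tau_ext: float = 82.0     # ms, extracellular decay
    d_z: float = 6.73         # µm, MIR attenuation depth at 3014 cm⁻¹
    capillary_depth: float = 20.0  # µm
    tau_bounds: tuple[float, float] = (10.0, 5000.0)  # ms


@dataclass
class PermeabilityResult:
    surface: float    # µm²
    volume: float     # µm³
    tau_mean: float   # ms
    p_d: float        # cm s⁻¹
    pixel_size: tuple[float, float] = (0.44, 0.44)


def height_from_phase(phase: np.ndarray, cal: HeightCalibration,
                      pixel_size: float = 0.44) -> np.ndarray:
    """Cell-height map (µm) from a MIR-OFF phase image in **radians**.

    The phase image is Gaussian low-pass filtered (σ in µm, converted to
    pixels) to extract the global cell shape, then scaled by λ/(2π Δn).
    Heights are clipped to [0, capillary depth]; substantial negative
    heights trigger a warning before clipping.
    """
    phase = np.asarray(phase, dtype=float)
    sigma_px = cal.lowpass_sigma / pixel_size
    smooth = gaussian_filter(phase, sigma_px) if sigma_px > 0 else phase
    h = smooth * cal.wavelength / (2.0 * math.pi * cal.delta_n)
    if np.any(h < -0.05 * cal.max_height):
        warnings.warn("strongly negative heights clipped to zero", stacklevel=2)
    return np.clip(h, 0.0, cal.max_height)


def contribution_ratio(h: np.ndarray | float, d_z: float = 6.73,
                       capillary_depth: float = 20.0) -> np.ndarray | float:
    """Extracellular contribution A(h) of a pixel with cell height h.

    Closed form of the ratio of Lambert–Beer weighted water columns:
    A(h) = (e^(−h/D_z) − e^(−L/D_z)) / (1 − e^(−L/D_z));
    A(0) = 1, A(L) = 0, strictly decreasing in h.
    """
    harr = np.asarray(h, dtype=float)
    if np.any(harr < 0) or np.any(harr > capillary_depth):
        raise ValueError("height outside [0, capillary depth]")
    edge = math.exp(-capillary_depth / d_z)
    a = (np.exp(-harr / d_z) - edge) / (1.0 - edge)
    return float(a) if np.isscalar(h) else a


def decay_curve(t: np.ndarray, a: float, tau: float, t0: float = 99.0,
                tau_ext: float = 82.0) -> np.ndarray:
    """Normalized biexponential exchange decay; 1 for t ≤ t₀."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t0, 0.0, None)
    return a * np.exp(-dt / tau_ext) + (1.0 - a) * np.exp(-dt / tau)


def fit_extracellular(series: ExchangeSeries, roi: tuple[int, int, int, int],
                      model: DecayModel | None = None) -> tuple[float, float]:
    """(t₀, τ_ext) from a cell-free region: single-exponential fit (A = 1).

    The ROI-mean trace is normalized by its pre-decay plateau; a series
    whose tail has not decayed below 80% of the plateau is rejected as
    non-decaying.
    """
    y0, x0, hh, ww = roi
    trace = series.frames[:, y0 : y0 + hh, x0 : x0 + ww].mean(axis=(1, 2))
    t = series.timestamps
    plateau = trace[t <= t[0] + (t[-1] - t[0]) * 0.05].mean()
    if plateau == 0 or trace[-1] > 0.8 * plateau:
        raise ValueError("extracellular trace does not decay; wrong ROI or no exchange")
    y = trace / plateau

    def f(tt, t0, tau):
        return decay_curve(tt, 1.0, tau, t0=t0, tau_ext=tau)

    guess_t0 = float(t[np.nonzero(y < 0.95)[0][0]])
    popt, _ = curve_fit(f, t, y, p0=[guess_t0, 100.0],
                        bounds=([t[0], 1.0], [t[-1], 1e4]))
    return float(popt[0]), float(popt[1])


def fit_decay_map(
    series: ExchangeSeries,
    height_map: np.ndarray,
    model: DecayModel | None = None,
    fit_start: float = 120.0,
    mask: np.ndarray | None = None,
    a_max: float = 0.995,
) -> tuple[np.ndarray, dict]:
    """Per-pixel intracellular decay time τ (ms).

    Frames are normalized per pixel by the pre-exchange (t < t₀) mean; A is
    fixed per pixel from the height map; τ is the only free parameter of a
    bounded least-squares fit (analytic Jacobian) restricted to
    t ≥ ``fit_start``.  Pixels with A > ``a_max`` (no cell: τ unidentifiable)
    or non-converged fits are NaN in the returned map and counted in the
    diagnostics dict.
    """
    model = model or DecayModel()
    t = series.timestamps
    sel = t >= fit_start
    if sel.sum() < 3:
        raise ValueError("fewer than 3 frames after fit_start")
    pre = t < model.t0
    if not np.any(pre):
        raise ValueError("no pre-exchange frames to normalize by")
    tt = t[sel] - model.t0
    lo, hi = model.tau_bounds

    baseline = series.frames[pre].mean(axis=0)
    a_map = contribution_ratio(height_map, model.d_z, model.capillary_depth)
    if mask is None:
        mask = np.ones(height_map.shape, dtype=bool)

    tau_map = np.full(height_map.shape, np.nan)
    n_flagged = 0
    n_failed = 0
    ext = np.exp(-tt / model.tau_ext)
    for iy, ix in zip(*np.nonzero(mask)):
        a = a_map[iy, ix]
        if a > a_max or baseline[iy, ix] == 0:
            n_flagged += 1
            continue
        y = series.frames[sel, iy, ix] / baseline[iy, ix]

        def resid(p):
            return a * ext + (1.0 - a) * np.exp(-tt / p[0]) - y

        def jac(p):
            return ((1.0 - a) * np.exp(-tt / p[0]) * tt / p[0] ** 2)[:, None]

        res = least_squares(resid, x0=[min(max(3.0 * model.tau_ext, lo * 1.1), hi * 0.9)],
                            jac=jac, bounds=([lo], [hi]))
        if not res.success:
            n_failed += 1
            continue
        tau_map[iy, ix] = res.x[0]
    diagnostics = {"n_fit": int(np.isfinite(tau_map).sum()),
                   "n_flagged_unidentifiable": n_flagged,
                   "n_failed": n_failed}
    return tau_map, diagnostics


def cell_mask(height_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixels belonging to the cell: low-passed height above ``threshold`` µm."""
    return np.asarray(height_map) > threshold


def surface_and_volume(
    height_map: np.ndarray,
    dx: float = 0.44,
    dy: float = 0.44,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Cell surface area S (µm²) and volume V (µm³) from the height map:

    S = Σ √(1 + (∂h/∂x)² + (∂h/∂y)²) Δx Δy,  V = Σ h Δx Δy,

    with central-difference gradients, summed over the cell mask.
    """
    h = np.asarray(height_map, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("height map must be finite")
    if mask is None:
        mask = np.ones(h.shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty cell mask")
    gy, gx = np.gradient(h, dy, dx)
    s_density = np.sqrt(1.0 + gx**2 + gy**2)
    s = float(np.sum(s_density[mask]) * dx * dy)
    v = float(np.sum(h[mask]) * dx * dy)
    return s, v


def permeability(tau_mean: float, surface: float, volume: float) -> float:
    """Diffusional water permeability P_d = 1/(τ (S/V)) in cm s⁻¹.

    τ in ms, S in µm², V in µm³; the µm/s result is converted by 1e-4.
    """
    if tau_mean <= 0 or surface <= 0 or volume <= 0:
        raise ValueError("tau, S and V must be positive")
    tau_s = tau_mean * 1e-3
    p_um_per_s = 1.0 / (tau_s * (surface / volume))
    return p_um_per_s * 1e-4
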