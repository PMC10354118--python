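"""Ground-truth generators for every stage of the analysis.

Each generator emulates the statistical structure the corresponding
analysis assumes — a smooth dome-shaped phantom cell with organelles on a
water background, Poisson-noise off-axis holograms, biexponential
H₂O/D₂O-exchange time series at 50 fps, and 3-component hyperspectral
stacks (CH₂ / CH₃-dominated / OH spectra) — and returns its ground truth
alongside the data.  A single seed fans out to independent per-stream
substreams via ``numpy`` ``SeedSequence.spawn`` in the order the streams
are drawn, so every output is reproducible under a fixed seed.

Default geometry: 256 × 256 pixels at 0.44 µm/pixel (a ~110-µm field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import PhaseMap
from .exchange import ExchangeSeries, contribution_ratio, decay_curve
from .holography import OffAxisConfig, SensorModel, synthesize_hologram
from .mcr import HyperspectralStack

__all__ = [
    "PhantomCell",
    "GeneratorConfig",
    "make_phantom_cell",
    "make_component_spectra",
    "make_hyperspectral",
    "make_exchange_series",
    "make_hologram_stack",
]

DEFAULT_SHAPE = (256, 256)
DEFAULT_PIXEL = 0.44  # µm


@dataclass
class PhantomCell:
    """Synthetic cell: height map, organelle masks, component maps."""

    height: np.ndarray                       # µm, ∈ [0, 20]
    masks: dict[str, np.ndarray]             # nucleus / nucleolus / droplets
    concentrations: dict[str, np.ndarray]    # lipid / protein / water, a.u.
    pixel_size: float = DEFAULT_PIXEL
    phase: np.ndarray | None = None          # rad, MIR-OFF phase image


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs shared by the generators; all stochastic outputs are
    reproducible under ``seed``."""

    seed: int = 0
    shape: tuple[int, int] = DEFAULT_SHAPE
    pixel_size: float = DEFAULT_PIXEL
    frame_rate: float = 50.0       # fps of MIP images
    phase_noise: float = 1.6       # mrad, per MIP frame
    delta_n: float = 0.0323
    wavelength: float = 0.532      # µm
    cell_height: float = 5.5       # µm peak
    cell_radius: float = 21.0      # µm footprint radius
    beam_fwhm: float = 87.0        # µm MIR spot


def _grids(shape: tuple[int, int], pixel: float) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel
    return np.meshgrid(y, x, indexing="ij")


def make_phantom_cell(config: GeneratorConfig = GeneratorConfig()) -> PhantomCell:
    """Dome-shaped cell with a nucleus, one nucleolus and extranuclear
    lipid droplets; returns the height map, masks, smooth concentration
    maps and the MIR-OFF phase image φ = 2π Δn h / λ (rad)."""
    yy, xx = _grids(config.shape, config.pixel_size)
    rho = np.hypot(yy, xx)
    dome = np.clip(1.0 - (rho / config.cell_radius) ** 2, 0.0, None) ** 1.5
    height = config.cell_height * dome

    nucleus = np.hypot(yy + 1.0, xx - 2.0) < 0.35 * config.cell_radius
    nucleolus = np.hypot(yy + 1.0, xx - 2.0) < 0.08 * config.cell_radius
    droplet_sites = [(-9.0, -8.0), (6.0, -11.0), (10.0, 7.0)]
    droplets = np.zeros(config.shape, dtype=bool)
    for cy, cx in droplet_sites:
        droplets |= np.hypot(yy - cy, xx - cx) < 1.5
    droplets &= ~nucleus  # lipid droplets are extranuclear
    cell = height > 0.5

    # smooth unit-height bumps for the concentration maps
    def soft(mask: np.ndarray, width_px: float) -> np.ndarray:
        from scipy.ndimage import gaussian_filter

        return gaussian_filter(mask.astype(float), width_px)

    lipid = soft(droplets, 1.5)
    protein = 0.25 * soft(cell & ~droplets, 2.0) + 0.75 * soft(nucleolus, 1.5) \
        + 0.35 * soft(nucleus, 2.0)
    water = np.clip(20.0 - height, 0.0, None) / 20.0  # residual water column

    phase = 2.0 * math.pi * config.delta_n * height / config.wavelength
    return PhantomCell(
        height=height,
        masks={"cell": cell, "nucleus": nucleus, "nucleolus": nucleolus, "droplets": droplets},
        concentrations={"lipid": lipid, "protein": protein, "water": water},
        pixel_size=config.pixel_size,
        phase=phase,
    )


#: (center cm⁻¹, FWHM cm⁻¹, relative amplitude) per band and component.
DEFAULT_PEAK_TABLE: dict[str, list[tuple[float, float, float]]] = {
    # symmetric + asymmetric CH₂ stretches
    "lipid": [(2854.0, 22.0, 0.7), (2925.0, 26.0, 1.0)],
    # CH₃-dominated with comparable CH₂ content (protein-like)
    "protein": [(2874.0, 24.0, 0.45), (2945.0, 26.0, 1.0), (2925.0, 24.0, 0.35)],
    # OH band: broad peak near 3400 cm⁻¹, rising through this window
    "water": [(3400.0, 260.0, 1.0)],
}


def make_component_spectra(
    wavenumbers: np.ndarray | None = None,
    peak_table: dict[str, list[tuple[float, float, float]]] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Component spectra as sums of Gaussian bands on a wavenumber axis.

    Defaults: 40 points over 2800–3250 cm⁻¹; CH₂ (2854 + 2925 cm⁻¹),
    CH₃-dominated (2945 cm⁻¹) and an OH band rising toward 3400 cm⁻¹.
    Bands narrower than the ~10 cm⁻¹ source linewidth are rejected.
    Components with all-zero amplitude are excluded.
    Returns (wavenumbers, spectra (n_components × n_k), names).
    """
    if wavenumbers is None:
        wavenumbers = np.linspace(2800.0, 3250.0, 40)
    k = np.asarray(wavenumbers, dtype=float)
    table = peak_table if peak_table is not None else DEFAULT_PEAK_TABLE
    spectra = []
    names = []
    for name, peaks in table.items():
        s = np.zeros_like(k)
        for center, fwhm, amp in peaks:
            if fwhm < 10.0:
                raise ValueError(f"{name}: band FWHM {fwhm} below the source linewidth")
            sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            s += amp * np.exp(-((k - center) ** 2) / (2.0 * sigma**2))
        if np.all(s == 0.0):
            continue
        spectra.append(s)
        names.append(name)
    return k, np.asarray(spectra), names


def make_hyperspectral(
    phantom: PhantomCell,
    spectra: np.ndarray | None = None,
    wavenumbers: np.ndarray | None = None,
    amplitudes: dict[str, float] | None = None,
    noise: float = 0.0,
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[HyperspectralStack, np.ndarray, np.ndarray]:
    """Forward model H(x, k) = Σ_i C_i(x) S_i(k) (+ noise) in mrad.

    ``amplitudes`` scales each component's concentration map so the signal
    magnitudes match the imaging regime (default: lipid 40 mrad at the CH₂
    peak in the droplets, protein 14 mrad at the nucleolus, water scaled to
    the extracellular column).  Returns (stack, C (n_pixels × n_c),
    S (n_c × n_k)); the noiseless stack equals C S exactly.
    """
    if spectra is None or wavenumbers is None:
        wavenumbers, spectra, names = make_component_spectra(wavenumbers)
    else:
        names = list(phantom.concentrations.keys())
    amplitudes = amplitudes or {"lipid": 40.0, "protein": 14.0, "water": 25.0}
    conc_maps = []
    for i, name in enumerate(names):
        cmap = phantom.concentrations[name]
        peak_value = cmap.max()
        scale = amplitudes.get(name, 1.0) / (peak_value * spectra[i].max()) if peak_value else 0.0
        conc_maps.append(cmap * scale)
    c = np.stack([m.ravel() for m in conc_maps], axis=1)
    clean = (c @ spectra).T.reshape(len(wavenumbers), *phantom.height.shape)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    frames = clean + rng.normal(0.0, noise, size=clean.shape) if noise > 0 else clean
    stack = HyperspectralStack(wavenumbers=wavenumbers, frames=frames)
    return stack, c, spectra


def make_exchange_series(
    phantom: PhantomCell,
    tau_map: np.ndarray | float = 420.0,
    t0: float = 99.0,
    tau_ext: float = 82.0,
    d_z: float = 6.73,
    frame_rate: float = 50.0,
    t_span: tuple[float, float] = (-200.0, 1600.0),
    noise: float = 0.0,
    amplitude: float = 60.0,
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[ExchangeSeries, dict]:
    """Biexponential H₂O/D₂O exchange movie at ``frame_rate`` fps (mrad).

    Per pixel, I(t) follows the two-component decay with A(h) from the
    phantom's height map; frames before t₀ sit on the pre-exchange plateau.
    ``noise`` is the per-frame Gaussian phase noise in mrad (the headline
    regime is 2% of the ~``amplitude``-mrad plateau).  Returns the series
    plus a ground-truth dict (tau map, A map, plateau amplitude).
    """
    dt = 1000.0 / frame_rate
    t = np.arange(t_span[0], t_span[1] + dt / 2, dt)
    h = phantom.height
    a_map = contribution_ratio(h, d_z=d_z)
    tau = np.broadcast_to(np.asarray(tau_map, dtype=float), h.shape)

    yy, xx = _grids(h.shape, phantom.pixel_size)
    sigma_beam = config.beam_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    beam = np.exp(-(yy**2 + xx**2) / (2.0 * sigma_beam**2))
    plateau = amplitude * beam

    frames = np.empty((t.size, *h.shape))
    dt_pos = np.clip(t - t0, 0.0, None)
    ext = np.exp(-dt_pos[:, None, None] / tau_ext)
    intra = np.exp(-dt_pos[:, None, None] / tau[None, :, :])
    frames = plateau[None] * (a_map[None] * ext + (1.0 - a_map)[None] * intra)
    if noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
        frames = frames + rng.normal(0.0, noise, size=frames.shape)
    series = ExchangeSeries(timestamps=t, frames=frames)
    truth = {"tau": np.array(tau), "a": a_map, "plateau": plateau,
             "t0": t0, "tau_ext": tau_ext, "height": h}
    return series, truth


def make_hologram_stack(
    phase: PhaseMap | np.ndarray,
    sensor: SensorModel,
    config: OffAxisConfig,
    n_electron: float,
    n_frames: int,
    seed: int = 0,
    quantize: bool = False,
) -> np.ndarray:
    """Stack of independent noisy holograms of the same phase image.

    Frame *i* uses the *i*-th spawn of the seed's ``SeedSequence``, so
    frames are independent and the stack is reproducible frame-by-frame.
    """
    children = np.random.SeedSequence(seed).spawn(n_frames)
    frames = [
        synthesize_hologram(phase, config, n_electron, sensor,
                            rng=np.random.default_rng(child), quantize=quantize)
        for child in children
    ]
    return np.stack(frames).astype(float)
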