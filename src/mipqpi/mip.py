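"""MIP image formation from MIR-ON/OFF phase frames and SNR metrics.

A MIP phase-change image is the difference between the phase images
captured with the MIR pump on and off; a background image of water without
cells can be subtracted to expose intracellular structure (at the cost of
√2 more noise), and the lateral MIR beam profile can be divided out using a
normalized water MIP image.  Noise is quantified as the spatial STD of a
20×20-pixel box; signal / noise defines the SNR.

Pixel indexing is 0-based row-major with origin at the top-left; boxes are
(y0, x0) origin plus size, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import PhaseMap

__all__ = [
    "MIPFramePair",
    "SNRReport",
    "mip_image",
    "subtract_water_background",
    "beam_profile_correct",
    "evaluate_snr",
    "demodulate_stream",
]


@dataclass
class MIPFramePair:
    """A registered MIR-ON / MIR-OFF phase-image pair (mrad)."""

    on_phase: PhaseMap
    off_phase: PhaseMap
    timestamp: float = 0.0  # ms

    def __post_init__(self) -> None:
        if self.on_phase.shape != self.off_phase.shape:
            raise ValueError("ON and OFF frames must have identical shapes")
        if self.on_phase.pixel_size != self.off_phase.pixel_size:
            raise ValueError("ON and OFF frames must share a pixel size")


@dataclass
class SNRReport:
    signal: float        # mrad
    noise: float         # mrad, spatial STD inside the noise box
    snr: float
    box_origin: tuple[int, int]


def mip_image(pair: MIPFramePair) -> PhaseMap:
    """MIP phase change Δθ = ON − OFF (mrad)."""
    return PhaseMap(
        values=pair.on_phase.values - pair.off_phase.values,
        pixel_size=pair.on_phase.pixel_size,
        wavelength=pair.on_phase.wavelength,
    )


def subtract_water_background(mip: PhaseMap, water_mip: PhaseMap) -> PhaseMap:
    """Pixelwise subtraction of a cell-free water MIP image.

    Removes the MIR-beam-shaped water background; independent noise in the
    two images makes the residual noise √2 times the single-image noise.
    """
    if mip.shape != water_mip.shape:
        raise ValueError("image and water background shapes differ")
    return PhaseMap(values=mip.values - water_mip.values,
                    pixel_size=mip.pixel_size, wavelength=mip.wavelength)


def beam_profile_correct(
    mip: PhaseMap, water_mip: PhaseMap, epsilon_fraction: float = 0.05
) -> PhaseMap:
    """Divide out the lateral MIR beam profile.

    The water MIP image is normalized to its maximum and used as a divisor;
    pixels where it falls below ``epsilon_fraction`` of the maximum are set
    to NaN (excluded from downstream statistics) to avoid noise blow-up at
    the beam skirts.
    """
    if mip.shape != water_mip.shape:
        raise ValueError("image and water background shapes differ")
    beam = water_mip.values / np.nanmax(water_mip.values)
    out = np.full_like(mip.values, np.nan)
    ok = beam >= epsilon_fraction
    if not np.any(ok):
        raise ValueError("beam-profile correction: every pixel below the mask threshold")
    out[ok] = mip.values[ok] / beam[ok]
    return PhaseMap(values=out, pixel_size=mip.pixel_size, wavelength=mip.wavelength)


def evaluate_snr(
    mip: PhaseMap,
    signal_pixel: tuple[int, int],
    noise_box: tuple[int, int],
    box_size: int = 20,
) -> SNRReport:
    """Signal at a pixel over the spatial STD of a ``box_size``² noise box.

    A zero-noise (degenerate) box yields infinite SNR with a warning rather
    than an error.
    """
    ny, nx = mip.shape
    y0, x0 = noise_box
    if y0 < 0 or x0 < 0 or y0 + box_size > ny or x0 + box_size > nx:
        raise ValueError("noise box outside the image")
    sy, sx = signal_pixel
    if not (0 <= sy < ny and 0 <= sx < nx):
        raise ValueError("signal pixel outside the image")
    box = mip.values[y0 : y0 + box_size, x0 : x0 + box_size]
    noise = float(np.nanstd(box, ddof=1))
    signal = float(mip.values[sy, sx])
    if noise == 0.0:
        warnings.warn("zero spatial STD in the noise box: SNR reported as inf", stacklevel=2)
        return SNRReport(signal=signal, noise=0.0, snr=float("inf"), box_origin=(y0, x0))
    return SNRReport(signal=signal, noise=noise, snr=signal / noise, box_origin=(y0, x0))


def demodulate_stream(
    frames: np.ndarray,
    pixel_size: float = 0.44,
    first_frame_on: bool = True,
    frame_interval_ms: float = 10.0,
) -> list[MIPFramePair]:
    """Pair a chopper-modulated phase-frame stream into (ON, OFF) pairs.

    The sensor alternates MIR-ON and MIR-OFF frames at twice the chopper
    rate, so the MIP image rate is half the sensor frame rate.  An odd
    trailing frame is dropped with a warning.  ``first_frame_on=False``
    swaps the chopper phase.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected a (frame, y, x) stack")
    n = frames.shape[0]
    if n % 2:
        warnings.warn("odd frame count: dropping the last frame", stacklevel=2)
        frames = frames[: n - 1]
    pairs = []
    for i in range(0, frames.shape[0], 2):
        on, off = (frames[i], frames[i + 1]) if first_frame_on else (frames[i + 1], frames[i])
        pairs.append(
            MIPFramePair(
                on_phase=PhaseMap(on, pixel_size=pixel_size),
                off_phase=PhaseMap(off, pixel_size=pixel_size),
                timestamp=i * frame_interval_ms,
            )
        )
    return pairs
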