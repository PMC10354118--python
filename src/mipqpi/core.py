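"""Shared light-weight containers for phase data.

Phase values are stored in **milliradians** in these containers; functions
that consume raw radian arrays (e.g. cell-height estimation) say so in their
docstrings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PhaseProfile:
    """Radially symmetric phase profile Δθ(x) (line-of-sight projection).

    ``x`` is the lateral distance from the symmetry axis in µm, ``values``
    the projected phase in mrad.
    """

    x: np.ndarray
    values: np.ndarray
    wavelength: float | None = None  # µm

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.x.shape != self.values.shape:
            raise ValueError("x and values must have identical shapes")


@dataclass
class PhaseMap:
    """A 2-D phase image in mrad with square pixels of ``pixel_size`` µm.

    NaN marks masked pixels (e.g. below the beam-profile threshold) and is
    excluded from downstream statistics; infinities are rejected.
    """

    values: np.ndarray
    pixel_size: float = 0.44
    wavelength: float | None = None  # µm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("PhaseMap values must be 2-D")
        if np.any(np.isinf(self.values)):
            raise ValueError("PhaseMap values must not be infinite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class TemperatureField:
    """Temperature rise ΔT (K) on a coordinate grid at time ``t`` (µs).

    ``coordinates`` is a 1-D radius array for spherically symmetric fields
    (the only case produced by the radial solver).
    """

    coordinates: np.ndarray
    values: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temperature field contains non-finite values")
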