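"""Hyperspectral MIP stack normalization and MCR-ALS unmixing.

A hyperspectral MIP stack H(x, k) (pixels × wavenumbers) is factorized as

    H = C S,   C ≥ 0 (n_pixels × n_components),  S ≥ 0 (n_components × n_k),

by alternating non-negative least squares: solve C given S, then S given C,
each by an active-set NNLS per row/column, until the relative residual
change falls below tolerance.  The residual is non-increasing by
construction.  Component identity follows the initialization order (no
sorting); tests that need to compare against ground truth handle the
permutation/scale ambiguity themselves.

Each component's share of the raw signal is

    R_i(x, k) = C_i(x) S_i(k) / Σ_j C_j(x) S_j(k) × Δ∅(x, k),

which sums to the raw stack exactly wherever the model is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "HyperspectralStack",
    "MCRModel",
    "normalize_stack",
    "mcr_als",
    "component_contribution",
    "pick_initial_spectra",
]


@dataclass
class HyperspectralStack:
    """One MIP phase-change frame (mrad) per wavenumber (cm⁻¹)."""

    wavenumbers: np.ndarray       # (n_k,), strictly increasing
    frames: np.ndarray            # (n_k, ny, nx)
    pulse_energy: np.ndarray | None = None  # (n_k,), µJ

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.frames.shape[0] != self.wavenumbers.size:
            raise ValueError("one frame per wavenumber required")
        if self.pulse_energy is not None:
            self.pulse_energy = np.asarray(self.pulse_energy, dtype=float)
            if self.pulse_energy.size != self.wavenumbers.size:
                raise ValueError("one pulse energy per wavenumber required")

    @property
    def n_k(self) -> int:
        return self.wavenumbers.size

    def as_matrix(self) -> np.ndarray:
        """(n_pixels, n_k) data matrix."""
        return self.frames.reshape(self.n_k, -1).T


@dataclass
class MCRModel:
    """Fitted factorization: concentrations, spectra, residual history."""

    concentrations: np.ndarray    # (n_pixels, n_components), ≥ 0
    spectra: np.ndarray           # (n_components, n_k), ≥ 0
    residuals: list = field(default_factory=list)
    image_shape: tuple[int, int] | None = None

    def concentration_maps(self) -> np.ndarray:
        if self.image_shape is None:
            raise ValueError("no image shape recorded")
        n_c = self.concentrations.shape[1]
        return self.concentrations.T.reshape(n_c, *self.image_shape)


def normalize_stack(
    stack: HyperspectralStack,
    water_stack: HyperspectralStack,
    pulse_energy: np.ndarray | None = None,
    reference_index: int = 0,
    epsilon_fraction: float = 0.05,
) -> HyperspectralStack:
    """Beam-profile and pulse-energy normalization.

    Per wavenumber, the cell stack is divided by the max-normalized water
    MIP image (beam-profile correction; pixels under ``epsilon_fraction``
    of the beam maximum become NaN) and rescaled by E(k_ref)/E(k) to remove
    the wavenumber-dependent MIR power variation.
    """
    if stack.n_k != water_stack.n_k or np.any(stack.wavenumbers != water_stack.wavenumbers):
        raise ValueError("cell and water stacks must share the wavenumber axis")
    energy = pulse_energy if pulse_energy is not None else stack.pulse_energy
    out = np.empty_like(stack.frames)
    for i in range(stack.n_k):
        beam = water_stack.frames[i] / np.nanmax(water_stack.frames[i])
        frame = np.where(beam >= epsilon_fraction, stack.frames[i] / beam, np.nan)
        if energy is not None:
            frame = frame * (energy[reference_index] / energy[i])
        out[i] = frame
    return HyperspectralStack(wavenumbers=stack.wavenumbers.copy(), frames=out,
                              pulse_energy=None if energy is None else np.full(stack.n_k, energy[reference_index]))


def _nnls_rows(basis: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Solve min ‖basis @ x − target‖ with x ≥ 0 for each target column.

    For small numbers of components the exact solution is found by
    enumerating support subsets (vectorized over all targets): the NNLS
    optimum is the feasible subset solution with the smallest residual.
    Falls back to Lawson–Hanson for wide bases.
    """
    k = basis.shape[1]
    n = targets.shape[1]
    if k > 8:
        out = np.empty((n, k))
        for j in range(n):
            out[j], _ = nnls(basis, targets[:, j])
        return out

    gram = basis.T @ basis
    rhs = basis.T @ targets                      # (k, n)
    best_obj = np.zeros(n)                       # empty support: x = 0, obj 0
    best_x = np.zeros((n, k))
    # objective up to the constant ‖b‖²: −xᵀ rhs (at the LS solution of a subset)
    for m in range(1, 2**k):
        support = [i for i in range(k) if m >> i & 1]
        sub = np.ix_(support, support)
        try:
            x_f = np.linalg.solve(gram[sub], rhs[support])  # (|F|, n)
        except np.linalg.LinAlgError:
            continue
        feasible = np.all(x_f >= -1e-12, axis=0)
        obj = -np.einsum("fn,fn->n", x_f, rhs[support])
        better = feasible & (obj < best_obj)
        if np.any(better):
            best_obj[better] = obj[better]
            cols = np.nonzero(better)[0]
            best_x[np.ix_(cols, support)] = x_f[:, better].T
            off = [i for i in range(k) if i not in support]
            if off:
                best_x[np.ix_(cols, off)] = 0.0
    np.clip(best_x, 0.0, None, out=best_x)
    return best_x


def mcr_als(
    data: HyperspectralStack | np.ndarray,
    init_spectra: np.ndarray,
    n_components: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MCRModel:
    """Alternating non-negative least squares factorization of H ≈ C S.

    ``init_spectra`` (n_components × n_k, ≥ 0, full rank) seeds S; the C
    and S updates alternate until the relative change of the Frobenius
    residual drops below ``tol`` or ``max_iter`` is reached.  NaN pixels
    (masked by normalization) are dropped from the fit and get NaN
    concentrations.
    """
    if isinstance(data, HyperspectralStack):
        matrix = data.as_matrix()
        image_shape = data.frames.shape[1:]
    else:
        matrix = np.asarray(data, dtype=float)
        image_shape = None
    init_spectra = np.asarray(init_spectra, dtype=float)
    if np.any(init_spectra < 0):
        raise ValueError("initial spectra must be non-negative")
    if n_components is None:
        n_components = init_spectra.shape[0]
    if init_spectra.shape != (n_components, matrix.shape[1]):
        raise ValueError("init_spectra must be (n_components, n_k)")
    if n_components > matrix.shape[1]:
        raise ValueError("more components than wavenumbers")
    if np.linalg.matrix_rank(init_spectra) < n_components:
        raise ValueError("rank-deficient initialization")

    good = np.all(np.isfinite(matrix), axis=1)
    d = matrix[good]

    s = init_spectra.copy()
    c = np.zeros((d.shape[0], n_components))
    residuals: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        c = _nnls_rows(s.T, d.T)                 # rows of C: min ‖S^T c − d‖
        s = _nnls_rows(c, d).T                   # columns of S: min ‖C s_k − d_k‖
        r = float(np.linalg.norm(d - c @ s))
        residuals.append(r)
        if prev < np.inf and abs(prev - r) <= tol * max(prev, 1e-30):
            break
        prev = r

    conc = np.full((matrix.shape[0], n_components), np.nan)
    conc[good] = c
    return MCRModel(concentrations=conc, spectra=s, residuals=residuals,
                    image_shape=image_shape)


def component_contribution(model: MCRModel, raw: HyperspectralStack | np.ndarray) -> np.ndarray:
    """Per-component contribution R_i(x, k) to the raw MIP phase change.

    Returns (n_components, n_pixels, n_k); Σ_i R_i equals the raw data
    exactly wherever the fitted model Σ_i C_i S_i is nonzero, and NaN where
    the model vanishes (flagged pixels).
    """
    matrix = raw.as_matrix() if isinstance(raw, HyperspectralStack) else np.asarray(raw, dtype=float)
    c = model.concentrations
    s = model.spectra
    if c.shape[0] != matrix.shape[0] or s.shape[1] != matrix.shape[1]:
        raise ValueError("model does not cover the raw stack's pixels/wavenumbers")
    parts = np.einsum("pi,ik->ipk", c, s)
    total = parts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total != 0.0, parts / total, np.nan)
    return share * matrix[None, :, :]


def pick_initial_spectra(
    stack: HyperspectralStack,
    rois: dict[str, tuple[int, int, int, int]],
    water_stack: HyperspectralStack | None = None,
    subtract_background: tuple[str, ...] = ("lipid", "nucleolus"),
) -> np.ndarray:
    """Initial spectra from labelled image ROIs (y0, x0, height, width).

    Intracellular ROIs (named in ``subtract_background``) use the
    water-background-subtracted stack; any other ROI (e.g. the
    extracellular one) uses the raw stack.  Each spectrum is the ROI-mean
    clipped at zero.  Empty ROIs are rejected; 1-pixel ROIs are allowed.
    """
    ny, nx = stack.frames.shape[1:]
    spectra = []
    for name, (y0, x0, hh, ww) in rois.items():
        if hh < 1 or ww < 1 or y0 < 0 or x0 < 0 or y0 + hh > ny or x0 + ww > nx:
            raise ValueError(f"roi {name!r} empty or outside the image")
        frames = stack.frames
        if name in subtract_background:
            if water_stack is None:
                raise ValueError(f"roi {name!r} requires a water stack for background subtraction")
            frames = stack.frames - water_stack.frames
        spec = frames[:, y0 : y0 + hh, x0 : x0 + ww].mean(axis=(1, 2))
        spectra.append(np.clip(spec, 0.0, None))
    return np.asarray(spectra)
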