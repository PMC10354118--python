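"""Readers/writers and validated run configuration.

Image stacks travel as multi-page TIFF (float32 or uint16) or HDF5 with
named datasets; curves as two-column CSV with a commented header.  Every
writer embeds a provenance block (package version, seed, config hash) —
TIFF in the ImageDescription tag, HDF5 as root attributes, CSV as comment
lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "read_stack",
    "write_stack",
    "read_curve",
    "write_curve",
    "read_hyperspectral_h5",
    "write_hyperspectral_h5",
]


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    log_level: str = "INFO"
    parameters: dict[str, Any] = {}
    paths: dict[str, str] = {}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig | dict) -> str:
    payload = config.model_dump() if isinstance(config, RunConfig) else config
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _provenance(seed: int | None, config: RunConfig | dict | None) -> dict:
    return {
        "package": "mipqpi",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }


def write_stack(
    path: str | Path,
    stack: np.ndarray,
    seed: int | None = None,
    config: RunConfig | dict | None = None,
) -> None:
    """Write a (frame, row, col) stack; .tif/.tiff → multi-page TIFF
    (float32 unless the input is uint16), .h5/.hdf5 → HDF5 ``/frames``."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (frame, row, col) stack")
    meta = _provenance(seed, config)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = stack if stack.dtype == np.uint16 else stack.astype(np.float32)
        tifffile.imwrite(path, data, description=json.dumps(meta))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("frames", data=stack)
            for key, val in meta.items():
                fh.attrs[key] = "" if val is None else val
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a stack written by :func:`write_stack` (lossless for float32)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            arr = fh["frames"][()]
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")
    return arr if arr.ndim == 3 else arr[None]


def write_curve(
    path: str | Path,
    t: np.ndarray,
    values: np.ndarray,
    t_unit: str = "us",
    value_unit: str = "norm",
    seed: int | None = None,
    config: RunConfig | dict | None = None,
) -> None:
    """Two-column CSV ``t,value`` with units in the header and a provenance
    comment block."""
    meta = _provenance(seed, config)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"t_{t_unit},value_{value_unit}\n")
        for ti, vi in zip(np.asarray(t), np.asarray(values)):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_curve(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a curve CSV; locale-independent (C-locale floats only)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] != 2 or not df.columns[0].startswith("t_"):
        raise ValueError("malformed curve file: expected a 't_<unit>,value_<unit>' header")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_hyperspectral_h5(
    path: str | Path,
    wavenumbers: np.ndarray,
    frames: np.ndarray,
    pulse_energy: np.ndarray | None = None,
    seed: int | None = None,
    config: RunConfig | dict | None = None,
) -> None:
    """HDF5 layout: /wavenumbers (cm⁻¹), /frames (n_k, ny, nx), optional
    /pulse_energy (µJ)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("wavenumbers", data=np.asarray(wavenumbers, dtype=float))
        fh.create_dataset("frames", data=np.asarray(frames, dtype=np.float32))
        if pulse_energy is not None:
            fh.create_dataset("pulse_energy", data=np.asarray(pulse_energy, dtype=float))
        for key, val in _provenance(seed, config).items():
            fh.attrs[key] = "" if val is None else val


def read_hyperspectral_h5(path: str | Path):
    from .mcr import HyperspectralStack

    with h5py.File(path, "r") as fh:
        return HyperspectralStack(
            wavenumbers=fh["wavenumbers"][()],
            frames=fh["frames"][()].astype(float),
            pulse_energy=fh["pulse_energy"][()] if "pulse_energy" in fh else None,
        )
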