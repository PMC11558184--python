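"""Reading and writing volumes, resistance series, and chamber descriptions.

Volumes travel as multi-page TIFF stacks, inlet slice first along the flow
axis (page k is the z = k slice, stored (y, x)), with a JSON sidecar
(``<stem>.json``) carrying the isotropic voxel size in micrometres, the
origin offset in mm, and whether the stack is a binary mask.  Resistance
series are CSV with columns time_min, dP_mmHg, Q_mL_min, R, lnR.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .hemodynamics import ResistanceSeries
from .volume import VoxelVolume

__all__ = ["write_volume", "read_volume", "write_series_csv", "read_series_csv"]

_SIDECAR_KEYS = ("voxel_size_um", "origin_mm", "binary")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF stack plus JSON metadata sidecar."""
    path = Path(path)
    grid = vol.grid
    if grid.dtype == bool:
        data = grid.astype(np.uint8)
    else:
        data = np.asarray(grid, dtype=np.float32)
    # (x, y, z) -> pages along z, each page (y, x)
    pages = np.transpose(data, (2, 1, 0))
    tifffile.imwrite(path, pages)
    meta = {
        "voxel_size_um": vol.voxel_size,
        "origin_mm": list(vol.origin),
        "binary": bool(grid.dtype == bool),
        "axis_order": "pages=z (inlet first), rows=y, cols=x",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a TIFF stack written by :func:`write_volume`.

    The JSON sidecar must be present and carry the isotropic voxel size;
    a missing or malformed sidecar is an explicit error.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {side} (voxel size is required)"
        )
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt metadata sidecar {side}: {exc}") from exc
    for key in _SIDECAR_KEYS:
        if key not in meta:
            raise ValueError(f"metadata sidecar {side} missing key {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    grid = np.transpose(pages, (2, 1, 0))
    if meta["binary"]:
        grid = grid.astype(bool)
    else:
        grid = grid.astype(np.float32)
    return VoxelVolume(
        grid=grid,
        voxel_size=float(meta["voxel_size_um"]),
        origin=tuple(meta["origin_mm"]),
    )


def write_series_csv(series: ResistanceSeries, path: str | Path) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    return path


def read_series_csv(path: str | Path, baseline_r0: float | None = None) -> ResistanceSeries:
    df = pd.read_csv(path)
    required = {"time_min", "dP_mmHg", "Q_mL_min"}
    if not required.issubset(df.columns):
        raise ValueError(f"series CSV missing columns {sorted(required - set(df.columns))}")
    return ResistanceSeries(
        times=df["time_min"].to_numpy(),
        dp=df["dP_mmHg"].to_numpy(),
        q=df["Q_mL_min"].to_numpy(),
        baseline_r0=baseline_r0,
    )
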