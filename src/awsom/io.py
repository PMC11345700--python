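"""NIfTI and text I/O helpers.

All volumes are written as NIfTI-1 with an affine encoding the isotropic
voxel size and the TR stored in the time-axis zoom; onset/duration schedules
use 2- or 3-column tab-separated text (FSL-style EV files).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import GridError

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_events",
    "read_events",
    "write_json",
    "check_same_grid",
]


def write_nifti(
    array: np.ndarray,
    path: str | Path,
    voxel_size_mm: float = 1.5,
    tr_s: float | None = None,
) -> Path:
    path = Path(path)
    data = np.asarray(array)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = [voxel_size_mm] * 3
    if data.ndim == 4:
        zooms.append(tr_s if tr_s is not None else 1.0)
    img.header.set_zooms(tuple(zooms))
    if data.ndim == 4 and tr_s is not None:
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, float, float | None]:
    """Return (data, voxel_size_mm, tr_s-or-None)."""
    img = nib.load(str(path))
    if img.ndim not in (3, 4):
        raise GridError(f"{path}: expected a 3D or 4D image, got {img.ndim}D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if img.ndim == 4 else None
    return np.asanyarray(img.dataobj), float(zooms[0]), tr


def check_same_grid(*arrays: np.ndarray) -> None:
    shapes = {a.shape[:3] for a in arrays}
    if len(shapes) > 1:
        raise GridError(f"grid mismatch between paired inputs: {sorted(shapes)}")


def write_events(onsets_s: np.ndarray, durations_s: np.ndarray, path: str | Path,
                 weights: np.ndarray | None = None) -> Path:
    path = Path(path)
    cols = [np.asarray(onsets_s, float), np.asarray(durations_s, float)]
    if weights is not None:
        cols.append(np.asarray(weights, float))
    np.savetxt(path, np.column_stack(cols), fmt="%.4f", delimiter="\t")
    return path


def read_events(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    table = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    return table[:, 0], table[:, 1]


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
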