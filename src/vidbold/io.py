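"""NIfTI and table input/output helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .synthdata import VolumeSeries


def save_volume_series(series: VolumeSeries, path: str | Path) -> Path:
    """Write a run as 4-D NIfTI (grid + time), TR recorded in the header."""
    path = Path(path)
    img_data = series.data.T.reshape(series.grid + (series.data.shape[0],))
    img = nib.Nifti1Image(np.asarray(img_data, dtype=np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr_s))
    nib.save(img, path)
    return path


def load_volume_series(path: str | Path, run_type: str = "") -> VolumeSeries:
    img = nib.load(str(path))
    data4d = np.asarray(img.dataobj, dtype=float)
    grid = data4d.shape[:3]
    data = data4d.reshape(-1, data4d.shape[3]).T
    tr = float(img.header.get_zooms()[3])
    return VolumeSeries(data=data, tr_s=tr, grid=grid, run_type=run_type)


def save_voxel_map(values: np.ndarray, grid: tuple[int, int, int], path: str | Path) -> Path:
    """Write a per-voxel scalar field (reliability, correlation, ...) as NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32).reshape(grid), affine=np.eye(4))
    nib.save(img, path)
    return path


def load_voxel_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float).ravel()
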