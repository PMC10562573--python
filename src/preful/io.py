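"""NIfTI and tabular I/O helpers.

Dynamic series are stored as 4D NIfTI volumes with shape (H, W, 1, T) —
time as the 4th dimension, the frame interval in the 4th pixdim — masks and
maps as 2D/3D volumes.  Tables (phase assignments, scores) are CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preproc import FrameSeries

__all__ = [
    "save_series",
    "load_series",
    "save_map",
    "load_map",
    "save_phase_table",
]


def save_series(series: FrameSeries, path) -> None:
    """Write a frame series as 4D NIfTI (H, W, 1, T)."""
    vol = np.transpose(series.data, (1, 2, 0))[:, :, None, :]
    img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.frame_interval))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_series(path, frame_interval: float | None = None) -> FrameSeries:
    """Read a 4D NIfTI series; the frame interval comes from the time pixdim
    unless overridden."""
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4D series, got shape {vol.shape}")
    if vol.shape[2] != 1:
        raise ValueError("expected a single-slice series (H, W, 1, T)")
    data = np.transpose(vol[:, :, 0, :], (2, 0, 1))
    if frame_interval is None:
        frame_interval = float(img.header.get_zooms()[3])
        if frame_interval <= 0:
            raise ValueError(
                "frame interval missing from the NIfTI header; pass it explicitly"
            )
    return FrameSeries(data, frame_interval=frame_interval,
                       slice_id=Path(str(path)).stem)


def save_map(arr: np.ndarray, path) -> None:
    """Write a 2D map or mask as NIfTI (bool becomes uint8)."""
    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr.astype(np.float32) if arr.dtype.kind == "f" else arr,
                             affine=np.eye(4)), str(path))


def load_map(path, as_bool: bool = False) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    arr = np.squeeze(arr)
    return arr.astype(bool) if as_bool else arr


def save_phase_table(times: np.ndarray, phases: np.ndarray, path) -> None:
    """CSV with one row per frame: index, acquisition time, cardiac phase."""
    pd.DataFrame(
        {"frame": np.arange(len(times)), "time_s": times, "phase": phases}
    ).to_csv(path, index=False)
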