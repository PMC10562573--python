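"""Frame-series intake, mask handling, search-ROI construction, and
respiratory high-pass filtering.

The perfusion-weighted PREFUL analysis starts from a spatially registered
free-breathing 2D time-series.  Before any cardiac-frequency analysis the
slow, large-amplitude respiratory signal component must be removed; this is
done with a zero-phase temporal high-pass filter (default cutoff 0.75 Hz,
between typical respiratory rates of ~0.2-0.4 Hz and cardiac rates of
~0.8-2 Hz).  Phase preservation matters because the filtered signal is
subsequently fitted for its cardiac phase, so the recursive filter is
applied forward-backward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import butter, filtfilt

log = logging.getLogger(__name__)

__all__ = [
    "FrameSeries",
    "SearchROI",
    "FilteredSeries",
    "build_search_roi",
    "high_pass",
    "check_registration",
]


@dataclass(frozen=True)
class FrameSeries:
    """A registered T x H x W dynamic image with a fixed frame interval.

    Parameters
    ----------
    data
        Signal values, shape (T, H, W); all values finite.
    frame_interval
        Time between consecutive frames in seconds.
    slice_id
        Identifier of the coronal slice this series belongs to.
    """

    data: np.ndarray
    frame_interval: float
    slice_id: str = "slice0"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[0] < 2:
            raise ValueError(
                f"frame series must be (T>=2, H, W), got shape {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("frame series contains non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame (s), starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def nyquist(self) -> float:
        return 0.5 / self.frame_interval


@dataclass(frozen=True)
class SearchROI:
    """The search region A_s: both lungs merged with the mediastinum.

    All blood-pool candidate voxels for cardiac phase estimation are drawn
    from this region.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError("search ROI is empty")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class FilteredSeries:
    """High-pass filtered series; per-voxel temporal mean is exactly zero."""

    data: np.ndarray
    cutoff: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def build_search_roi(
    lung_mask: np.ndarray,
    mediastinum_mask: np.ndarray | None = None,
    *,
    max_closing_radius: int = 25,
) -> SearchROI:
    """Merge lungs and mediastinum into the search region A_s.

    When no mediastinum mask is available, the gap between the two lungs is
    bridged by morphological closing (dilation followed by erosion) with the
    smallest disk radius that makes the union connected, so that blood-pool
    voxels in the mediastinal gap remain reachable.

    Parameters
    ----------
    lung_mask
        Binary H x W mask of both lungs; must be nonempty.
    mediastinum_mask
        Optional binary mask of the mediastinum; same shape as ``lung_mask``.
    max_closing_radius
        Upper bound on the closing radius searched in the fallback path.
    """
    lung = np.asarray(lung_mask, dtype=bool)
    if not lung.any():
        raise ValueError("lung mask is empty")
    if mediastinum_mask is not None:
        med = np.asarray(mediastinum_mask, dtype=bool)
        if med.shape != lung.shape:
            raise ValueError(
                f"mask shape mismatch: lung {lung.shape} vs mediastinum {med.shape}"
            )
        return SearchROI(lung | med)

    n_comp = ndimage.label(lung)[1]
    if n_comp <= 1:
        return SearchROI(lung.copy())
    for radius in range(1, max_closing_radius + 1):
        closed = _disk_closing(lung, radius)
        if ndimage.label(closed)[1] == 1:
            return SearchROI(closed)
    log.warning(
        "lung components not bridged within closing radius %d; "
        "using union without closing", max_closing_radius,
    )
    return SearchROI(lung.copy())


def _disk_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing with an explicit disk: dilation then erosion."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (yy**2 + xx**2) <= radius**2
    dilated = ndimage.binary_dilation(mask, structure=disk)
    return ndimage.binary_erosion(dilated, structure=disk)


def high_pass(
    series: FrameSeries,
    cutoff: float = 0.75,
    *,
    order: int = 5,
) -> FilteredSeries:
    """Remove respiration-induced signal variations with a zero-phase
    temporal high-pass filter.

    A Butterworth high-pass of the given order is applied per voxel
    forward-backward (``filtfilt``) with reflective edge padding of at least
    three cutoff periods, so pass-band phase is preserved (required because
    cardiac phases are fitted downstream).  The residual per-voxel temporal
    mean of the finite record is subtracted afterwards so the output is
    exactly DC-free.

    Raises
    ------
    ValueError
        If ``cutoff`` is at or above the Nyquist frequency of the series.
    """
    fs = series.sampling_rate
    nyq = series.nyquist
    if cutoff >= nyq:
        raise ValueError(
            f"high-pass cutoff {cutoff:g} Hz is at/above the Nyquist frequency "
            f"{nyq:g} Hz of the series (frame interval {series.frame_interval:g} s)"
        )
    b, a = butter(order, cutoff, btype="highpass", fs=fs)
    # >= 3 cutoff periods of reflective padding, bounded by the record length
    padlen = min(series.n_frames - 2, max(int(np.ceil(3 * fs / cutoff)), 3 * order))
    out = filtfilt(b, a, series.data, axis=0, padlen=padlen)
    out = out - out.mean(axis=0, keepdims=True)
    return FilteredSeries(out, cutoff=cutoff, frame_interval=series.frame_interval)


def check_registration(
    series: FrameSeries, lung_mask: np.ndarray, *, tolerance: float = 1.0
) -> float:
    """Coarse registration sanity check (registration itself is external).

    Estimates the translation of each frame relative to the first by phase
    cross-correlation within the bounding box of the lung mask (robust to
    the respiration-induced *intensity* modulation that remains in a
    well-registered series) and logs a warning if the drift exceeds
    ``tolerance`` voxels.  Returns the maximum drift (voxels).
    """
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        raise ValueError("lung mask is empty")
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    box = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    ref = series.data[0][box]
    # integer-voxel phase correlation against the first frame, subsampled in
    # time (a coarse check only needs a handful of frames)
    step = max(1, series.n_frames // 16)
    ref_f = np.fft.rfft2(ref - ref.mean())
    drift = 0.0
    for frame in series.data[::step]:
        mov = frame[box]
        cross = np.fft.irfft2(ref_f * np.conj(np.fft.rfft2(mov - mov.mean())),
                              s=ref.shape)
        peak = np.unravel_index(np.argmax(np.abs(cross)), cross.shape)
        shift = np.array(peak, dtype=float)
        shift[shift > np.array(ref.shape) / 2] -= np.array(ref.shape)[
            shift > np.array(ref.shape) / 2
        ]
        drift = max(drift, float(np.hypot(*shift)))
    if drift > tolerance:
        log.warning(
            "lung center-of-mass drift %.2f voxels exceeds %.1f; "
            "series may not be well registered", drift, tolerance,
        )
    return float(drift)
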