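"""Cardiac phase sorting: blood-pool cluster detection (R_sort), piecewise
sinusoidal phase fitting, cluster pruning, and interpolation of the frame
series onto an equidistant cardiac-cycle grid.

This is the heart of the perfusion-weighted analysis.  Free-breathing
frames sample the cardiac cycle asynchronously; instead of ECG gating, the
cardiac phase of every frame is estimated from the signal of fully
blood-filled voxels.  Candidates are voxels whose temporal standard
deviation (M_std) and temporal maximum intensity projection (M_MIP) both
exceed the 98th percentile within the search region A_s.  The candidates
form connected clusters (R_sort); their spatially averaged signal is fitted
with a piecewise sinusoid, clusters whose removal improves the fit are
pruned iteratively, and each frame is assigned a cardiac phase in [0, 1)
from the fit.  Finally the frames are sorted by phase and interpolated onto
15 equidistant phases covering one cardiac cycle (a nominal temporal
resolution of 50 ms at a heart rate of 80 bpm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.signal import periodogram

from .preproc import FilteredSeries, SearchROI

log = logging.getLogger(__name__)

__all__ = [
    "FeatureMaps",
    "SortROI",
    "SineFit",
    "PhaseResolvedSeries",
    "NoCardiacSignalError",
    "compute_feature_maps",
    "select_candidates",
    "cluster_candidates",
    "fit_phase_signal",
    "prune_clusters",
    "assign_phases",
    "sort_to_cycle",
    "nominal_temporal_resolution",
]

DEFAULT_CARDIAC_BAND = (0.5, 2.0)


class NoCardiacSignalError(RuntimeError):
    """No usable cardiac-frequency signal was found in the search band."""


@dataclass(frozen=True)
class FeatureMaps:
    """Per-voxel temporal SD (M_std) and temporal MIP (M_MIP) over A_s.

    Values are NaN outside the search region.
    """

    m_std: np.ndarray
    m_mip: np.ndarray
    roi: SearchROI


@dataclass(frozen=True)
class SortROI:
    """The blood-pool candidate clusters R_sort.

    ``labels`` is an H x W integer map: 0 = background, 1..n_clusters =
    cluster id.  Clusters are connected components of the candidate voxel
    set (4-connectivity by default).
    """

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("R_sort must contain at least one cluster")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        return self.labels == cluster_id

    @property
    def cluster_ids(self) -> list[int]:
        return [int(i) for i in np.unique(self.labels) if i > 0]

    def subset(self, keep: set[int]) -> "SortROI":
        labels = np.where(np.isin(self.labels, sorted(keep)), self.labels, 0)
        return SortROI(labels=labels, n_clusters=len(keep))


@dataclass(frozen=True)
class SineFit:
    """Result of the piecewise sinusoidal fit to the R_sort mean signal.

    A single cardiac frequency is shared across all pieces; amplitude,
    phase offset and baseline are free per piece to absorb heart-rate and
    amplitude drift.  ``gof`` is the coefficient of determination of the
    full piecewise model.  ``pieces`` holds (start, stop, amplitude,
    phase_offset, baseline) per piece with frame-index ranges.
    """

    frequency: float
    amplitude: float
    phase_offset: float
    baseline: float
    gof: float
    pieces: tuple
    gof_adjusted: float = 0.0
    low_confidence: bool = False


@dataclass(frozen=True)
class PhaseResolvedSeries:
    """The cardiac-cycle image stack: P equidistant phases in [0, 1)."""

    data: np.ndarray  # (P, H, W)
    phase_grid: np.ndarray  # (P,)

    @property
    def n_phases(self) -> int:
        return self.data.shape[0]


def compute_feature_maps(filtered: FilteredSeries, roi: SearchROI) -> FeatureMaps:
    """Temporal SD and MIP maps of the filtered signal over A_s."""
    if roi.mask.shape != filtered.data.shape[1:]:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match series "
            f"spatial shape {filtered.data.shape[1:]}"
        )
    m_std = np.where(roi.mask, filtered.data.std(axis=0), np.nan)
    m_mip = np.where(roi.mask, filtered.data.max(axis=0), np.nan)
    return FeatureMaps(m_std=m_std, m_mip=m_mip, roi=roi)


def select_candidates(maps: FeatureMaps, percentile: float = 0.98) -> np.ndarray:
    """Voxels strictly above the given percentile of both M_std and M_MIP.

    The percentile is computed over A_s with linear interpolation between
    order statistics; selection is by strict inequality, so a degenerate
    region where all values tie selects nothing.

    Raises
    ------
    ValueError
        If the intersection is empty (e.g. uniform maps); the message
        suggests lowering the percentile.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    roi = maps.roi.mask
    thr_std = np.quantile(maps.m_std[roi], percentile)
    thr_mip = np.quantile(maps.m_mip[roi], percentile)
    selected = roi & (maps.m_std > thr_std) & (maps.m_mip > thr_mip)
    if not selected.any():
        raise ValueError(
            f"no voxel exceeds the {percentile:.0%} percentile of both M_std "
            "and M_MIP; try a lower percentile"
        )
    return selected


def cluster_candidates(voxels: np.ndarray, connectivity: int = 1) -> SortROI:
    """Group candidate voxels into connected clusters (R_sort).

    ``connectivity`` 1 = 4-connectivity (default), 2 = 8-connectivity.
    Singleton clusters are allowed.
    """
    voxels = np.asarray(voxels, dtype=bool)
    if not voxels.any():
        raise ValueError("candidate voxel set is empty")
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(voxels, structure=structure)
    return SortROI(labels=labels, n_clusters=n)


def _piece_slices(n: int, piece_len: int) -> list[slice]:
    """Contiguous windows of ``piece_len`` frames; a short tail is merged."""
    starts = list(range(0, n, piece_len))
    slices = []
    for s in starts:
        e = min(s + piece_len, n)
        slices.append(slice(s, e))
    if len(slices) > 1 and (slices[-1].stop - slices[-1].start) < piece_len // 2:
        last = slices.pop()
        prev = slices.pop()
        slices.append(slice(prev.start, last.stop))
    return slices


def _piecewise_ssr(
    freq: float, t: np.ndarray, y: np.ndarray, slices: list[slice]
) -> tuple[float, list[tuple]]:
    """Least-squares residual of the shared-frequency piecewise sinusoid.

    Per piece, amplitude/phase/baseline follow from a linear fit of
    a*sin(2*pi*f*t) + b*cos(2*pi*f*t) + c.
    """
    ssr = 0.0
    pieces = []
    for sl in slices:
        ts, ys = t[sl], y[sl]
        theta = 2 * np.pi * freq * ts
        design = np.column_stack([np.sin(theta), np.cos(theta), np.ones_like(ts)])
        coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
        resid = ys - design @ coef
        ssr += float(resid @ resid)
        a, b, c = coef
        pieces.append(
            (sl.start, sl.stop, float(np.hypot(a, b)), float(np.arctan2(b, a)), float(c))
        )
    return ssr, pieces


def fit_phase_signal(
    signal: np.ndarray,
    frame_interval: float,
    *,
    cardiac_band: tuple[float, float] = DEFAULT_CARDIAC_BAND,
    piecewise: bool = True,
    min_piece_frames: int = 12,
) -> SineFit:
    """Fit a (piecewise) sinusoid to a blood-pool signal time series.

    The cardiac frequency is initialized at the periodogram peak within
    ``cardiac_band``, then refined by 1-D bounded optimization of the
    piecewise least-squares residual.  Pieces are contiguous windows of
    about one cardiac cycle but never fewer than ``min_piece_frames``
    frames (so each piece constrains its three linear parameters); with
    ``piecewise=False`` a single global sinusoid is fitted.

    gof is the coefficient of determination (1 - SSR/SST) over all pieces.
    Because the piecewise model has three linear parameters per piece, a
    pure-noise signal still yields a nonzero gof; the ``low_confidence``
    flag therefore uses the degrees-of-freedom-adjusted coefficient
    (``gof_adjusted``), which stays near zero on noise, with a 0.2 cutoff.

    Raises
    ------
    NoCardiacSignalError
        If the band holds no periodogram bin or the signal carries no power.
    """
    y = np.asarray(signal, dtype=float)
    n = y.size
    t = np.arange(n) * frame_interval
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise NoCardiacSignalError("no cardiac signal detected: signal is constant")

    freqs, power = periodogram(y, fs=1.0 / frame_interval)
    in_band = (freqs >= cardiac_band[0]) & (freqs <= cardiac_band[1])
    if not in_band.any():
        raise NoCardiacSignalError(
            f"no cardiac signal detected: no spectral bin inside the band "
            f"{cardiac_band[0]:g}-{cardiac_band[1]:g} Hz at resolution "
            f"{freqs[1]:g} Hz"
        )
    if power[in_band].max() == 0.0:
        raise NoCardiacSignalError(
            "no cardiac signal detected: zero spectral power in the cardiac band"
        )
    f0 = float(freqs[in_band][np.argmax(power[in_band])])

    period_frames = max(2, int(round(1.0 / (f0 * frame_interval))))
    piece_len = max(period_frames, min_piece_frames) if piecewise else n
    slices = _piece_slices(n, piece_len)

    df = freqs[1] - freqs[0]
    lo = max(cardiac_band[0], f0 - 2 * df)
    hi = min(cardiac_band[1], f0 + 2 * df)
    res = minimize_scalar(
        lambda f: _piecewise_ssr(f, t, y, slices)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    freq = float(res.x)
    ssr, pieces = _piecewise_ssr(freq, t, y, slices)
    gof = float(np.clip(1.0 - ssr / sst, 0.0, 1.0))
    n_params = 3 * len(pieces) + 1  # per-piece amp/phase/baseline + frequency
    dof = max(n - n_params, 1)
    gof_adj = float(np.clip(1.0 - (ssr / dof) / (sst / (n - 1)), 0.0, 1.0))
    amps = np.array([p[2] for p in pieces])
    return SineFit(
        frequency=freq,
        amplitude=float(amps.mean()),
        phase_offset=pieces[0][3],
        baseline=float(np.mean([p[4] for p in pieces])),
        gof=gof,
        pieces=tuple(pieces),
        gof_adjusted=gof_adj,
        low_confidence=gof_adj < 0.2,
    )


def _mean_signal(filtered: FilteredSeries, mask: np.ndarray) -> np.ndarray:
    return filtered.data[:, mask].mean(axis=1)


def prune_clusters(
    sort_roi: SortROI,
    filtered: FilteredSeries,
    **fit_kwargs,
) -> tuple[SortROI, SineFit, list[dict]]:
    """Iteratively remove R_sort clusters whose removal improves the fit.

    Greedy one-at-a-time loop: fit the spatially averaged signal of the
    current R_sort, test each cluster's removal, remove the cluster whose
    removal improves the goodness of fit the most, and repeat until no
    removal helps or a single cluster remains.  At least one cluster always
    survives.  Returns the pruned R_sort, the final fit, and a log of
    pruning steps (cluster id, gof before/after).
    """
    keep = set(sort_roi.cluster_ids)
    current = sort_roi
    fit = fit_phase_signal(
        _mean_signal(filtered, current.mask), filtered.frame_interval, **fit_kwargs
    )
    prune_log: list[dict] = []
    while len(keep) > 1:
        best_id, best_fit = None, fit
        for cid in sorted(keep):
            trial_mask = current.mask & (current.labels != cid)
            trial_fit = fit_phase_signal(
                _mean_signal(filtered, trial_mask), filtered.frame_interval, **fit_kwargs
            )
            if trial_fit.gof > best_fit.gof + 1e-12:
                best_id, best_fit = cid, trial_fit
        if best_id is None:
            break
        keep.remove(best_id)
        prune_log.append(
            {"removed_cluster": best_id, "gof_before": fit.gof, "gof_after": best_fit.gof}
        )
        log.info(
            "pruned R_sort cluster %d: gof %.4f -> %.4f",
            best_id, fit.gof, best_fit.gof,
        )
        fit = best_fit
        current = sort_roi.subset(keep)
    return current, fit, prune_log


def assign_phases(fit: SineFit, frame_times: np.ndarray) -> np.ndarray:
    """Cardiac phase in [0, 1) for each frame.

    phase(t) = frac(f * t + phi / 2*pi), with the phase offset of the piece
    the frame falls in (phases are continuous across pieces when the fit is
    coherent).
    """
    t = np.asarray(frame_times, dtype=float)
    phases = np.empty_like(t)
    for start, stop, _amp, phi, _c in fit.pieces:
        sl = slice(start, stop)
        phases[sl] = np.mod(fit.frequency * t[sl] + phi / (2 * np.pi), 1.0)
    return phases


def sort_to_cycle(
    filtered: FilteredSeries,
    phases: np.ndarray,
    n_phases: int = 15,
) -> PhaseResolvedSeries:
    """Sort frames by cardiac phase and resample one cycle at ``n_phases``
    equidistant phases.

    Frames are ordered by phase, frames at near-identical phases (the same
    circular phase bin of width ``1/n_phases``) are averaged — which is
    what suppresses frame noise, since a typical series visits each phase
    many times — and the bin means are then transferred onto the exact
    equidistant grid by circular linear interpolation between the mean bin
    phases.  The result is invariant to frame order.

    Raises
    ------
    ValueError
        If fewer than ``n_phases / 2`` distinct phases are available
        ("insufficient phase coverage").
    """
    if n_phases < 3:
        raise ValueError("n_phases must be >= 3")
    phases = np.asarray(phases, dtype=float)
    if phases.shape[0] != filtered.data.shape[0]:
        raise ValueError("one phase per frame required")
    if np.any((phases < 0) | (phases >= 1)):
        raise ValueError("phases must lie in [0, 1)")

    n_distinct = len(np.unique(np.round(phases / 1e-6).astype(np.int64)))
    if n_distinct < n_phases / 2:
        raise ValueError(
            f"insufficient phase coverage: {n_distinct} distinct phases "
            f"for {n_phases} requested"
        )

    # circular bin k collects phases within 1/(2 n_phases) of grid point k/n
    bins = np.round(phases * n_phases).astype(np.int64) % n_phases
    occupied = np.unique(bins)
    counts = np.bincount(bins, minlength=n_phases)[occupied]
    t_len, h, w = filtered.data.shape
    summed = np.zeros((n_phases, h, w))
    np.add.at(summed, bins, filtered.data)
    values = summed[occupied] / counts[:, None, None]
    # circular mean phase of each occupied bin, expressed near its grid point
    delta = np.mod(phases - bins / n_phases + 0.5, 1.0) - 0.5
    delta_sum = np.bincount(bins, weights=delta, minlength=n_phases)[occupied]
    sample_phases = np.mod(occupied / n_phases + delta_sum / counts, 1.0)
    order = np.argsort(sample_phases)
    sample_phases = sample_phases[order]
    values = values[order]

    # wrap one sample on each side for circular interpolation
    ext_phases = np.concatenate(
        [[sample_phases[-1] - 1.0], sample_phases, [sample_phases[0] + 1.0]]
    )
    ext_values = np.concatenate([values[-1:], values, values[:1]], axis=0)

    grid = np.arange(n_phases) / n_phases
    idx = np.searchsorted(ext_phases, grid)
    left, right = ext_phases[idx - 1], ext_phases[idx]
    weight = np.where(right > left, (grid - left) / (right - left), 0.0)
    data = (1 - weight)[:, None, None] * ext_values[idx - 1] + weight[
        :, None, None
    ] * ext_values[idx]
    return PhaseResolvedSeries(data=data, phase_grid=grid)


def nominal_temporal_resolution(heart_rate_bpm: float, n_phases: int = 15) -> float:
    """Duration of one phase bin in seconds (e.g. 50 ms at 80 bpm, 15 phases)."""
    return 60.0 / heart_rate_bpm / n_phases
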