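"""Perfusion quantification: Q, S_Blood, normalized perfusion Q_N, and the
perfusion defect percentage QDP.

Q is the cardiac-cycle signal amplitude of the lung parenchyma, read from
the phase-resolved stack.  S_Blood is the same amplitude in fully
blood-filled voxels (the pruned R_sort), so Q_N = 100 * Q / S_Blood is a
percentage that cancels scanner scaling and coil sensitivity common to both.
Voxels with Q_N below a threshold (default 2% of the blood-pool amplitude)
count as perfusion defects; QDP is their percentage of the analyzed
parenchyma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phase_sorting import PhaseResolvedSeries, SortROI

log = logging.getLogger(__name__)

__all__ = [
    "QMap",
    "QNMap",
    "QDPResult",
    "compute_q",
    "compute_sblood",
    "compute_qn",
    "compute_qdp",
]

DEFAULT_QDP_THRESHOLD = 2.0  # percent of the blood-pool amplitude


def _cycle_amplitude(data: np.ndarray, convention: str) -> np.ndarray:
    """Per-voxel cardiac-cycle amplitude.

    ``ptp``: peak-to-trough (max - min) over the phase dimension (default).
    ``first_harmonic``: 2x the magnitude of the first Fourier harmonic
    across the cycle, i.e. the peak-to-trough of the fundamental.
    """
    if convention == "ptp":
        return data.max(axis=0) - data.min(axis=0)
    if convention == "first_harmonic":
        spec = np.fft.rfft(data, axis=0) / data.shape[0]
        return 4.0 * np.abs(spec[1])
    raise ValueError(f"unknown amplitude convention {convention!r}")


@dataclass(frozen=True)
class QMap:
    """Per-voxel cardiac-cycle amplitude on the lung mask (NaN elsewhere)."""

    values: np.ndarray
    lung_mask: np.ndarray
    convention: str = "ptp"


@dataclass(frozen=True)
class QNMap:
    """Per-voxel normalized perfusion in percent; NaN outside the lung."""

    values: np.ndarray
    lung_mask: np.ndarray
    s_blood: float

    def median(self) -> float:
        return float(np.nanmedian(self.values[self.lung_mask]))

    def mean(self) -> float:
        return float(np.nanmean(self.values[self.lung_mask]))


@dataclass(frozen=True)
class QDPResult:
    """Perfusion defect percentage and the underlying defect mask."""

    qdp: float
    threshold: float
    n_defect: int
    n_parenchyma: int
    defect_mask: np.ndarray


def compute_q(
    cycle: PhaseResolvedSeries,
    lung_mask: np.ndarray,
    *,
    convention: str = "ptp",
) -> QMap:
    """Cardiac-cycle signal amplitude per parenchymal voxel."""
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        raise ValueError("lung mask is empty")
    if mask.shape != cycle.data.shape[1:]:
        raise ValueError("lung mask shape does not match the cycle stack")
    amp = _cycle_amplitude(cycle.data, convention)
    return QMap(values=np.where(mask, amp, np.nan), lung_mask=mask, convention=convention)


def compute_sblood(
    cycle: PhaseResolvedSeries,
    sort_roi: SortROI,
    *,
    convention: str = "ptp",
) -> float:
    """Blood-pool normalizer: the cycle amplitude of a fully blood-filled
    voxel, averaged over the pruned R_sort.

    Averaging over the surviving clusters (rather than taking a single
    voxel) makes the normalizer robust to intra-ROI signal variability.
    The amplitude convention must match :func:`compute_q` so that the
    Q_N ratio is convention-free.
    """
    mask = sort_roi.mask
    if not mask.any():
        raise ValueError("R_sort is empty")
    amp = _cycle_amplitude(cycle.data, convention)
    s_blood = float(amp[mask].mean())
    if s_blood <= 0:
        raise ValueError("no blood signal: R_sort amplitude is non-positive")
    return s_blood


def compute_qn(q: QMap, s_blood: float) -> QNMap:
    """Normalized perfusion Q_N = 100 * Q / S_Blood (percent)."""
    if s_blood <= 0:
        raise ValueError("s_blood must be positive")
    return QNMap(values=100.0 * q.values / s_blood, lung_mask=q.lung_mask, s_blood=s_blood)


def compute_qdp(
    qn: QNMap,
    lung_mask: np.ndarray | None = None,
    threshold: float = DEFAULT_QDP_THRESHOLD,
) -> QDPResult:
    """Perfusion defect percentage: share of parenchyma with Q_N below
    ``threshold`` percent.

    Voxels with undefined Q_N (no phase coverage) are excluded from both
    numerator and denominator and logged.
    """
    mask = np.asarray(lung_mask if lung_mask is not None else qn.lung_mask, dtype=bool)
    if not mask.any():
        raise ValueError("lung mask is empty")
    values = qn.values
    analyzed = mask & np.isfinite(values)
    n_dropped = int(mask.sum() - analyzed.sum())
    if n_dropped:
        log.info("excluding %d lung voxels with undefined Q_N from QDP", n_dropped)
    defect = analyzed & (values < threshold)
    n_par = int(analyzed.sum())
    n_def = int(defect.sum())
    return QDPResult(
        qdp=100.0 * n_def / n_par,
        threshold=float(threshold),
        n_defect=n_def,
        n_parenchyma=n_par,
        defect_mask=defect,
    )
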