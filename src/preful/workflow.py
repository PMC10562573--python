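"""Pipeline orchestration: configuration, the end-to-end slice/study run
(filtering -> blood-pool detection -> phase sorting -> Q_N/QDP -> scoring),
and cohort-level evaluation against a reference standard.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .perfusion import (
    QDPResult,
    QNMap,
    compute_q,
    compute_qdp,
    compute_qn,
    compute_sblood,
)
from .phase_sorting import (
    PhaseResolvedSeries,
    SineFit,
    SortROI,
    assign_phases,
    cluster_candidates,
    compute_feature_maps,
    fit_phase_signal,
    prune_clusters,
    select_candidates,
    sort_to_cycle,
)
from .preproc import FrameSeries, build_search_roi, check_registration, high_pass
from .scoring import (
    PatientCall,
    call_patient,
    score_all_segments,
    score_lobes,
    scores_to_frame,
)
from .stats import (
    cohen_kappa,
    confusion_from_scores,
    contingency_from_calls,
    diagnostic_metrics,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SliceResult", "StudyResult", "run_slice",
           "run_study", "evaluate_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the analysis.

    Defaults are the standard perfusion-weighted PREFUL settings: 0.75 Hz
    respiratory high-pass, 98th-percentile blood-pool candidate selection,
    15 cardiac phases, 2% Q_N defect threshold, 75% segmental rule with a
    5% subsegmental floor, and a 0.5-2.0 Hz cardiac search band.
    """

    cutoff_hz: float = 0.75
    percentile: float = 0.98
    n_phases: int = 15
    qdp_threshold_percent: float = 2.0
    cardiac_band: tuple[float, float] = (0.5, 2.0)
    connectivity: int = 1
    piecewise: bool = True
    score_floor: float = 0.05
    amplitude_convention: str = "ptp"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if self.n_phases < 3:
            raise ValueError("n_phases must be >= 3")
        if self.qdp_threshold_percent < 0:
            raise ValueError("qdp threshold must be >= 0")
        if self.cardiac_band[0] <= 0 or self.cardiac_band[0] >= self.cardiac_band[1]:
            raise ValueError("cardiac_band must be (low, high) with 0 < low < high")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        if not 0 <= self.score_floor <= 0.75:
            raise ValueError("score_floor must be in [0, 0.75]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cardiac_band"] = list(self.cardiac_band)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "cardiac_band" in d:
            d["cardiac_band"] = tuple(d["cardiac_band"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        """Stable short hash embedded in every output for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SliceResult:
    """All per-slice artifacts of one pipeline run."""

    slice_id: str
    sort_roi: SortROI
    fit: SineFit
    phases: np.ndarray
    cycle: PhaseResolvedSeries
    qn: QNMap
    qdp: QDPResult
    s_blood: float
    prune_log: list
    registration_drift: float
    config_hash: str


@dataclass
class StudyResult:
    """Cross-slice study result: union defect mask, scores, patient call."""

    slices: list[SliceResult]
    defect_mask: np.ndarray
    segment_scores: dict
    lobe_scores: dict
    call: PatientCall
    config_hash: str


def run_slice(
    series: FrameSeries,
    lung_mask: np.ndarray,
    mediastinum_mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> SliceResult:
    """Run the perfusion pipeline on one registered slice.

    Deterministic given inputs and config.  When ``out_dir`` is given, all
    intermediate artifacts (R_sort mask, phase table, 15-phase stack, Q_N
    map, defect mask, summary CSV) are written there; filenames embed the
    config hash.
    """
    cfg = config or PipelineConfig()
    drift = check_registration(series, lung_mask)
    roi = build_search_roi(lung_mask, mediastinum_mask)
    log.info("slice %s: search ROI of %d voxels", series.slice_id, roi.n_voxels)

    filtered = high_pass(series, cfg.cutoff_hz)
    maps = compute_feature_maps(filtered, roi)
    candidates = select_candidates(maps, cfg.percentile)
    sort_roi = cluster_candidates(candidates, connectivity=cfg.connectivity)
    log.info(
        "slice %s: %d candidate voxels in %d clusters",
        series.slice_id, int(candidates.sum()), sort_roi.n_clusters,
    )
    sort_roi, fit, prune_log = prune_clusters(
        sort_roi, filtered,
        cardiac_band=cfg.cardiac_band, piecewise=cfg.piecewise,
    )
    log.info(
        "slice %s: pruned to %d clusters, f_card=%.3f Hz, gof=%.3f",
        series.slice_id, sort_roi.n_clusters, fit.frequency, fit.gof,
    )
    phases = assign_phases(fit, filtered.times)
    cycle = sort_to_cycle(filtered, phases, cfg.n_phases)

    q = compute_q(cycle, lung_mask, convention=cfg.amplitude_convention)
    s_blood = compute_sblood(cycle, sort_roi, convention=cfg.amplitude_convention)
    qn = compute_qn(q, s_blood)
    qdp = compute_qdp(qn, lung_mask, cfg.qdp_threshold_percent)
    log.info(
        "slice %s: S_Blood=%.2f, median Q_N=%.2f%%, QDP=%.2f%%",
        series.slice_id, s_blood, qn.median(), qdp.qdp,
    )

    result = SliceResult(
        slice_id=series.slice_id,
        sort_roi=sort_roi,
        fit=fit,
        phases=phases,
        cycle=cycle,
        qn=qn,
        qdp=qdp,
        s_blood=s_blood,
        prune_log=prune_log,
        registration_drift=drift,
        config_hash=cfg.config_hash,
    )
    if out_dir is not None:
        _write_slice(result, filtered.times, cfg, Path(out_dir))
    return result


def _write_slice(res: SliceResult, times, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{res.slice_id}_{res.config_hash}"
    pio.save_map(res.sort_roi.labels.astype(np.int16), out / f"{tag}_rsort.nii.gz")
    pio.save_phase_table(times, res.phases, out / f"{tag}_phases.csv")
    pio.save_map(np.transpose(res.cycle.data, (1, 2, 0)), out / f"{tag}_cycle.nii.gz")
    pio.save_map(np.nan_to_num(res.qn.values), out / f"{tag}_qn.nii.gz")
    pio.save_map(res.qdp.defect_mask, out / f"{tag}_defect.nii.gz")
    summary = pd.DataFrame(
        [{
            "slice_id": res.slice_id,
            "median_qn_percent": res.qn.median(),
            "mean_qn_percent": res.qn.mean(),
            "qdp_percent": res.qdp.qdp,
            "n_parenchyma": res.qdp.n_parenchyma,
            "s_blood": res.s_blood,
            "f_card_hz": res.fit.frequency,
            "gof": res.fit.gof,
            "config_hash": res.config_hash,
        }]
    )
    summary.to_csv(out / f"{tag}_summary.csv", index=False)
    _render_qn_png(res.qn, out / f"{tag}_qn.png")


def _render_qn_png(qn: QNMap, path: Path) -> None:
    """Color-coded perfusion-weighted map for visual review."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    img = np.ma.masked_invalid(qn.values)
    im = ax.imshow(img, cmap="inferno", vmin=0, vmax=max(20.0, float(img.max())))
    fig.colorbar(im, ax=ax, label="Q_N (%)")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_study(
    slices: list[tuple[FrameSeries, np.ndarray, np.ndarray | None]],
    segment_map: np.ndarray,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Run the pipeline on all slices of a patient and score the patient.

    Per-slice defect masks are unioned across slices before segmental
    scoring (a 2D-reading convention: a defect visible on any slice counts
    against the segment), then the 18 segments are scored 0/1/2 and the
    patient-level embolism call applied.
    """
    cfg = config or PipelineConfig()
    results = [
        run_slice(series, lung, med, cfg, out_dir=out_dir)
        for series, lung, med in slices
    ]
    defect_union = np.zeros_like(results[0].qdp.defect_mask, dtype=bool)
    for r in results:
        defect_union |= r.qdp.defect_mask
    seg_scores = score_all_segments(defect_union, segment_map, floor=cfg.score_floor)
    lobe_scores = score_lobes(seg_scores)
    call = call_patient(seg_scores)
    log.info(
        "patient call: %s (%d segmental, %d subsegmental)",
        "positive" if call.positive else "negative",
        call.n_segmental, call.n_subsegmental,
    )
    result = StudyResult(
        slices=results,
        defect_mask=defect_union,
        segment_scores=seg_scores,
        lobe_scores=lobe_scores,
        call=call,
        config_hash=cfg.config_hash,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame = scores_to_frame("patient", seg_scores, lobe_scores, call)
        frame["config_hash"] = cfg.config_hash
        frame.to_csv(out / f"scores_{cfg.config_hash}.csv", index=False)
    return result


def evaluate_cohort(
    patient_calls: pd.DataFrame,
    region_scores: pd.DataFrame | None = None,
) -> dict:
    """Study-style agreement report from paired test/reference tables.

    Parameters
    ----------
    patient_calls
        Columns ``patient_id``, ``test`` (bool), ``reference`` (bool).
    region_scores
        Optional long table with columns ``patient_id``, ``region_id``,
        ``level`` (``lobe``/``segment``), ``test`` (0/1/2),
        ``reference`` (0/1/2).  Binary detection per region is score > 0;
        the 3x3 classification matrix is built from the segment rows.

    Returns a JSON-serializable dict with 2x2 tables, diagnostic metrics,
    and kappas per level, plus the 3x3 classification kappa when segment
    scores are provided.

    Raises
    ------
    ValueError
        If any record lacks its pair (NaN in test/reference), listing the
        offending ids.
    """
    report: dict = {}

    def _check_paired(df: pd.DataFrame, keys: list[str]) -> None:
        bad = df[df[["test", "reference"]].isna().any(axis=1)]
        if len(bad):
            offenders = bad[keys].astype(str).agg("/".join, axis=1).tolist()
            raise ValueError(f"unpaired records: {offenders}")

    _check_paired(patient_calls, ["patient_id"])
    table = contingency_from_calls(
        patient_calls["test"].astype(bool), patient_calls["reference"].astype(bool)
    )
    kap = cohen_kappa(table)
    report["patient"] = {
        "table": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "metrics": diagnostic_metrics(table).as_dict(),
        "kappa": kap.kappa,
        "kappa_ci": list(kap.ci),
        "band": kap.band,
    }

    if region_scores is not None:
        _check_paired(region_scores, ["patient_id", "region_id"])
        for level in ("lobe", "segment"):
            sub = region_scores[region_scores["level"] == level]
            if not len(sub):
                continue
            table = contingency_from_calls(
                sub["test"].to_numpy() > 0, sub["reference"].to_numpy() > 0
            )
            kap = cohen_kappa(table)
            report[level] = {
                "table": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
                "metrics": diagnostic_metrics(table).as_dict(),
                "kappa": kap.kappa,
                "kappa_ci": list(kap.ci),
                "band": kap.band,
            }
        seg = region_scores[region_scores["level"] == "segment"]
        if len(seg):
            conf = confusion_from_scores(
                seg["test"].astype(int), seg["reference"].astype(int)
            )
            kap = cohen_kappa(conf)
            report["classification"] = {
                "matrix": conf.counts.astype(int).tolist(),
                "labels": list(conf.labels),
                "kappa": kap.kappa,
                "kappa_ci": list(kap.ci),
                "band": kap.band,
            }
    return report
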