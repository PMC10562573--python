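"""Regional defect scoring: per-segment 0/1/2 classification, per-lobe
aggregation, and the per-patient embolism call.

The scoring mirrors clinical reading of perfusion maps against an
18-segment lung model (10 right, 8 left): a hypoperfused area covering more
than 75% of a segment is "segmental" (score 2); a smaller but non-trivial
one is "subsegmental" (score 1); otherwise the segment is normal (score 0).
A patient is called positive for pulmonary embolism when at least one
segmental or at least two subsegmental defects are present (EANM-style
rule).  Because visual readers implicitly ignore speckle, an explicit
minimum defect fraction (default 5% of the segment area) separates score 1
from score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionScore",
    "PatientCall",
    "LOBES",
    "SEGMENT_LABELS",
    "score_segment",
    "score_all_segments",
    "score_lobe",
    "score_lobes",
    "call_patient",
    "scores_to_frame",
]

SEGMENTAL_FRACTION = 0.75  # strictly more than this => segmental defect
DEFAULT_SCORE_FLOOR = 0.05

N_SEGMENTS = 18

#: segment labels 1..10 are right-lung (R1..R10), 11..18 left-lung (L1..L8)
SEGMENT_LABELS = {i: (f"R{i}" if i <= 10 else f"L{i - 10}") for i in range(1, 19)}

#: standard five-lobe grouping of the 18 segments
LOBES = {
    "right_upper": (1, 2, 3),
    "right_middle": (4, 5),
    "right_lower": (6, 7, 8, 9, 10),
    "left_upper": (11, 12, 13, 14),
    "left_lower": (15, 16, 17, 18),
}


@dataclass(frozen=True)
class RegionScore:
    """Defect classification of one region (segment or lobe).

    score 0 = no hypoperfused area, 1 = subsegmental, 2 = segmental.
    """

    region_id: str
    score: int
    defect_fraction: float
    area: int


@dataclass(frozen=True)
class PatientCall:
    """Patient-level embolism call from the 18 segment scores."""

    positive: bool
    n_segmental: int
    n_subsegmental: int


def score_segment(
    defect_mask: np.ndarray,
    segment_map: np.ndarray,
    segment_id: int,
    floor: float = DEFAULT_SCORE_FLOOR,
) -> RegionScore:
    """Score one lung segment from the defect mask.

    f = |defect ∩ segment| / |segment|; score 2 if f > 0.75 (strict),
    score 1 if floor <= f <= 0.75, score 0 below the floor.
    """
    segment = np.asarray(segment_map) == segment_id
    area = int(segment.sum())
    if area == 0:
        raise ValueError(f"segment {segment_id} has zero area in the segment map")
    f = float((np.asarray(defect_mask, dtype=bool) & segment).sum()) / area
    if f > SEGMENTAL_FRACTION:
        score = 2
    elif f >= floor:
        score = 1
    else:
        score = 0
    return RegionScore(
        region_id=SEGMENT_LABELS.get(segment_id, str(segment_id)),
        score=score,
        defect_fraction=f,
        area=area,
    )


def score_all_segments(
    defect_mask: np.ndarray,
    segment_map: np.ndarray,
    floor: float = DEFAULT_SCORE_FLOOR,
) -> dict[int, RegionScore]:
    """Score every segment present in the 18-segment map."""
    return {
        sid: score_segment(defect_mask, segment_map, sid, floor=floor)
        for sid in range(1, N_SEGMENTS + 1)
        if (np.asarray(segment_map) == sid).any()
    }


def score_lobe(member_scores: list[RegionScore], lobe_id: str) -> RegionScore:
    """Aggregate segment scores into a lobe score.

    Lobe score is the maximum member score; the lobe defect fraction is the
    area-weighted mean of the member fractions.
    """
    if not member_scores:
        raise ValueError("a lobe needs at least one member segment")
    areas = np.array([s.area for s in member_scores], dtype=float)
    fracs = np.array([s.defect_fraction for s in member_scores])
    return RegionScore(
        region_id=lobe_id,
        score=max(s.score for s in member_scores),
        defect_fraction=float((areas * fracs).sum() / areas.sum()),
        area=int(areas.sum()),
    )


def score_lobes(segment_scores: dict[int, RegionScore]) -> dict[str, RegionScore]:
    """Lobe scores for the standard five-lobe grouping."""
    out = {}
    for lobe_id, members in LOBES.items():
        present = [segment_scores[m] for m in members if m in segment_scores]
        if present:
            out[lobe_id] = score_lobe(present, lobe_id)
    return out


def call_patient(segment_scores: dict[int, RegionScore]) -> PatientCall:
    """Positive if >= 1 segmental (score 2) or >= 2 subsegmental (score 1)
    defects are present among the 18 segments."""
    if len(segment_scores) != N_SEGMENTS:
        raise ValueError(
            f"expected {N_SEGMENTS} segment scores, got {len(segment_scores)}"
        )
    n2 = sum(1 for s in segment_scores.values() if s.score == 2)
    n1 = sum(1 for s in segment_scores.values() if s.score == 1)
    return PatientCall(positive=(n2 >= 1) or (n1 >= 2), n_segmental=n2, n_subsegmental=n1)


def scores_to_frame(
    patient_id: str,
    segment_scores: dict[int, RegionScore],
    lobe_scores: dict[str, RegionScore] | None = None,
    call: PatientCall | None = None,
) -> pd.DataFrame:
    """Long-format score table: one row per region plus the patient row."""
    rows = [
        {
            "patient_id": patient_id,
            "region_id": s.region_id,
            "level": "segment",
            "score": s.score,
            "defect_fraction": s.defect_fraction,
        }
        for s in segment_scores.values()
    ]
    for s in (lobe_scores or {}).values():
        rows.append(
            {
                "patient_id": patient_id,
                "region_id": s.region_id,
                "level": "lobe",
                "score": s.score,
                "defect_fraction": s.defect_fraction,
            }
        )
    if call is not None:
        rows.append(
            {
                "patient_id": patient_id,
                "region_id": "patient",
                "level": "patient",
                "score": int(call.positive),
                "defect_fraction": float("nan"),
            }
        )
    return pd.DataFrame(rows)
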