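"""Bundled contingency tables from a published 77-patient validation cohort
comparing perfusion-weighted PREFUL MRI against V/Q SPECT/CT for chronic
pulmonary embolism.

The tables are the printed cross-classification counts of that study
(patient-, lobe- and segment-level detection of hypoperfused areas, and the
3x3 defect-classification matrix over all 77 x 18 = 1386 lung segments).
They serve as regression fixtures for the agreement layer: every statistic
the package computes from them can be checked against the study's reported
numbers.
"""

from __future__ import annotations

import numpy as np

from .stats import BinaryContingency, ConfusionMatrix

__all__ = [
    "N_PATIENTS",
    "N_SEGMENTS_PER_PATIENT",
    "patient_table",
    "lobe_table",
    "segment_table",
    "classification_table",
    "cohort_tables",
]

N_PATIENTS = 77
N_SEGMENTS_PER_PATIENT = 18


def patient_table() -> BinaryContingency:
    """Patient-level calls: 36 reference-positive, 41 reference-negative;
    the MRI read gave 2 false positives and 1 false negative."""
    return BinaryContingency(tp=35, fp=2, fn=1, tn=39)


def lobe_table() -> BinaryContingency:
    """Lobe-level detection over 77 patients x 5 lobes = 385 lobes."""
    return BinaryContingency(tp=143, fp=14, fn=14, tn=214)


def segment_table() -> BinaryContingency:
    """Segment-level detection over 77 x 18 = 1386 segments."""
    return BinaryContingency(tp=364, fp=53, fn=63, tn=906)


def classification_table() -> ConfusionMatrix:
    """3x3 defect-classification counts over all 1386 segments.

    Rows: MRI read; columns: reference standard; categories: absent,
    subsegmental, segmental hypoperfusion.
    """
    counts = np.array(
        [
            [906, 44, 9],
            [49, 89, 42],
            [14, 73, 160],
        ]
    )
    return ConfusionMatrix(counts=counts, labels=("absent", "subsegmental", "segmental"))


def cohort_tables() -> dict:
    """All bundled tables keyed by level."""
    return {
        "patient": patient_table(),
        "lobe": lobe_table(),
        "segment": segment_table(),
        "classification": classification_table(),
    }
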