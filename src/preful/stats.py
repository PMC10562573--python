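"""Diagnostic agreement statistics: contingency metrics with exact binomial
confidence intervals, unweighted Cohen's kappa, and agreement banding.

These are the statistics used to compare a test modality (here PW-PREFUL
MRI) against a reference standard (V/Q SPECT/CT) at the patient, lobe, and
segment levels, and to quantify chance-corrected agreement of the 0/1/2
defect-classification scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BinaryContingency",
    "ConfusionMatrix",
    "Proportion",
    "DiagnosticMetrics",
    "KappaResult",
    "diagnostic_metrics",
    "cohen_kappa",
    "agreement_band",
    "contingency_from_calls",
    "confusion_from_scores",
]

AGREEMENT_BANDS = ("slight", "fair", "moderate", "substantial", "almost perfect")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BinaryContingency:
    """2x2 cross-classification of test vs reference calls."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_matrix(self) -> np.ndarray:
        """Rows = test (positive, negative); columns = reference."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K cross-classification with category labels (K >= 2)."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1] or counts.shape[0] < 2:
            raise ValueError("confusion matrix must be square, K >= 2")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("confusion matrix is empty")
        if len(self.labels) != counts.shape[0]:
            raise ValueError("one label per category required")
        object.__setattr__(self, "counts", counts.astype(float))


@dataclass(frozen=True)
class Proportion:
    """A reported proportion: integer percent with a 95% CI, plus raw counts."""

    percent: int
    ci: tuple[int, int]
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy with 95% CIs.

    A metric whose denominator is zero is ``None`` and listed in
    ``undefined``.
    """

    sensitivity: Proportion | None
    specificity: Proportion | None
    ppv: Proportion | None
    npv: Proportion | None
    accuracy: Proportion | None
    undefined: tuple = ()

    def as_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            p: Proportion | None = getattr(self, name)
            out[name] = None if p is None else {
                "percent": p.percent,
                "ci": list(p.ci),
                "fraction": f"{p.numerator}/{p.denominator}",
            }
        return out


@dataclass(frozen=True)
class KappaResult:
    """Unweighted Cohen's kappa with large-sample 95% CI and agreement band."""

    kappa: float
    se: float
    ci: tuple[float, float]
    band: str
    undefined: bool = False


def _proportion(num: int, den: int) -> Proportion | None:
    """Point estimate and exact (Clopper-Pearson) 95% CI, as integer percents."""
    if den == 0:
        return None
    lo, hi = proportion_confint(num, den, alpha=0.05, method="beta")
    return Proportion(
        percent=_round_half_up(100.0 * num / den),
        ci=(_round_half_up(100.0 * lo), _round_half_up(100.0 * hi)),
        numerator=num,
        denominator=den,
    )


def diagnostic_metrics(t: BinaryContingency) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from a 2x2 table.

    Confidence intervals use the exact binomial (Clopper-Pearson) method;
    point estimates and bounds are rounded half-up to integer percents for
    reporting (the raw counts remain available on each
    :class:`Proportion`).
    """
    pieces = {
        "sensitivity": _proportion(t.tp, t.tp + t.fn),
        "specificity": _proportion(t.tn, t.tn + t.fp),
        "ppv": _proportion(t.tp, t.tp + t.fp),
        "npv": _proportion(t.tn, t.tn + t.fn),
        "accuracy": _proportion(t.tp + t.tn, t.total),
    }
    undefined = tuple(k for k, v in pieces.items() if v is None)
    return DiagnosticMetrics(**pieces, undefined=undefined)


def cohen_kappa(m: ConfusionMatrix | BinaryContingency | np.ndarray) -> KappaResult:
    """Unweighted Cohen's kappa with its large-sample standard error.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    (trace / total) and p_e the chance agreement from the marginals.  The
    95% CI is kappa +/- 1.96 * SE (asymptotic SE for unweighted kappa),
    clipped to [-1, 1].  When all mass sits in a single cell p_e = 1 and
    kappa is undefined (returned as NaN with ``undefined=True``).
    """
    if isinstance(m, BinaryContingency):
        counts = m.as_matrix().astype(float)
    elif isinstance(m, ConfusionMatrix):
        counts = m.counts
    else:
        counts = np.asarray(m, dtype=float)
        ConfusionMatrix(counts, tuple(range(counts.shape[0])))  # validate
    n = counts.sum()
    p_o = np.trace(counts) / n
    p_e = float(counts.sum(axis=1) @ counts.sum(axis=0)) / n**2
    if p_e >= 1.0 - 1e-15:
        return KappaResult(
            kappa=float("nan"), se=float("nan"), ci=(float("nan"), float("nan")),
            band="undefined", undefined=True,
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(_sm_cohens_kappa(counts, return_results=True).std_kappa)
    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return KappaResult(kappa=float(kappa), se=se, ci=(lo, hi), band=agreement_band(kappa))


def agreement_band(kappa: float) -> str:
    """Agreement interpretation band for a kappa value.

    almost perfect for kappa strictly above 0.8; substantial 0.60-0.80;
    moderate 0.40-0.59; fair 0.20-0.39; slight below 0.20 (including
    negative values).  Exactly 0.80 falls in "substantial" because the
    almost-perfect band requires kappa to exceed 0.8.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa > 0.8:
        return "almost perfect"
    if kappa >= 0.60:
        return "substantial"
    if kappa >= 0.40:
        return "moderate"
    if kappa >= 0.20:
        return "fair"
    return "slight"


def contingency_from_calls(test, reference) -> BinaryContingency:
    """2x2 table from paired boolean calls (test vs reference standard)."""
    test = np.asarray(test, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if test.shape != reference.shape:
        raise ValueError("test and reference call vectors differ in length")
    return BinaryContingency(
        tp=int((test & reference).sum()),
        fp=int((test & ~reference).sum()),
        fn=int((~test & reference).sum()),
        tn=int((~test & ~reference).sum()),
    )


def confusion_from_scores(test, reference, labels=(0, 1, 2)) -> ConfusionMatrix:
    """K x K matrix from paired categorical scores (rows = test)."""
    test = np.asarray(test)
    reference = np.asarray(reference)
    if test.shape != reference.shape:
        raise ValueError("test and reference score vectors differ in length")
    k = len(labels)
    counts = np.zeros((k, k))
    index = {lab: i for i, lab in enumerate(labels)}
    for a, b in zip(test, reference):
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels))
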