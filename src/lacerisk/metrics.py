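"""Screening metrics and group-comparison statistics.

The high-risk LACE flag is evaluated against 30-day unplanned
readmission as a 2x2 screening problem (sensitivity, specificity, PPV,
NPV, accuracy with an exact binomial CI, prevalence, no-information
rate).  Cohort tables comparing unplanned readmissions against all other
patients use Welch two-sample t-tests for continuous variables and
Yates-corrected Pearson chi-square for 2x2 categorical tables; both are
also available directly from printed summary cells (n, mean, SD or 2x2
counts), which is how reported statistics can be checked without the
raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "ClassificationMetrics",
    "GroupSummary",
    "ComparisonResult",
    "confusion_matrix",
    "reconstruct_confusion",
    "classification_metrics",
    "welch_t_from_summary",
    "chi2_2x2",
    "compare_groups",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts: positive = unplanned readmission, flagged = high LACE."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class ClassificationMetrics:
    """Derived screening metrics; a metric with a zero denominator is None."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    accuracy_ci: tuple[float, float]
    prevalence: float
    nir: float
    flagged_rate: float


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class ComparisonResult:
    kind: str  # welch_t | student_t | chi2_2x2
    statistic: float
    df: float
    p: float
    summaries: tuple = field(default=())


def confusion_matrix(flags: Sequence, outcomes: Sequence) -> ConfusionMatrix:
    """Cross-tabulate boolean high-risk flags against boolean outcomes."""
    f = np.asarray(flags, dtype=bool)
    y = np.asarray(outcomes, dtype=bool)
    if f.shape != y.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {y.shape}")
    if f.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(f & y)),
        fp=int(np.sum(f & ~y)),
        fn=int(np.sum(~f & y)),
        tn=int(np.sum(~f & ~y)),
    )


def reconstruct_confusion(
    n_positive: int, n_negative: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Rebuild integer 2x2 counts from reported sensitivity/specificity.

    Published screening tables usually print sensitivity, specificity and
    the group sizes but not the underlying counts; rounding each cell to
    the nearest integer recovers the matrix those proportions came from.
    """
    tp = round(sensitivity * n_positive)
    tn = round(specificity * n_negative)
    return ConfusionMatrix(tp=tp, fp=n_negative - tn, fn=n_positive - tp, tn=tn)


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning,
                      stacklevel=3)
        return None
    return num / den


def classification_metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> ClassificationMetrics:
    """Screening metrics with an exact (Clopper-Pearson) accuracy CI.

    Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), PPV = tp/(tp+fp),
    NPV = tn/(tn+fn), accuracy = (tp+tn)/n; the no-information rate is the
    majority-class proportion.  Metrics with zero denominators are reported
    as None (with a warning) rather than coerced to 0.
    """
    if cm.n == 0:
        raise ValueError("cannot compute metrics for an empty matrix")
    prevalence = cm.n_positive / cm.n
    correct = cm.tp + cm.tn
    low, high = proportion_confint(correct, cm.n, alpha=alpha, method="beta")
    return ClassificationMetrics(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        ppv=_ratio(cm.tp, cm.tp + cm.fp, "ppv"),
        npv=_ratio(cm.tn, cm.tn + cm.fn, "npv"),
        accuracy=correct / cm.n,
        accuracy_ci=(float(low), float(high)),
        prevalence=prevalence,
        nir=max(prevalence, 1 - prevalence),
        flagged_rate=cm.n_flagged / cm.n,
    )


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> ComparisonResult:
    """Welch two-sample t-test from (n, mean, SD) summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with Welch-Satterthwaite
    degrees of freedom and a two-sided p-value.
    """
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if v1 + v2 == 0:
        raise ValueError("both groups have zero variance; t undefined")
    t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return ComparisonResult("welch_t", float(t), float(df), float(p),
                            summaries=(g1, g2))


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = True) -> ComparisonResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1.

    Yates continuity correction is applied by default, matching how 2x2
    cohort tables are conventionally reported.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal total")
    res = stats.chi2_contingency(table, correction=correction)
    return ComparisonResult("chi2_2x2", float(res.statistic), float(res.dof),
                            float(res.pvalue))


_CONTINUOUS = (("age", "age"), ("los_days", "los"),
               ("cci", "comorbidity_score"), ("lace_total", "lace_score"))


def compare_groups(frame: pd.DataFrame) -> dict[str, ComparisonResult]:
    """Unplanned-readmission vs other group comparisons for one cohort.

    ``frame`` holds one admission per row with an ``outcome`` column
    ("unplanned_readmission" vs "other") plus age, los_days, cci,
    lace_total, sex and admission_type.  Continuous variables get Welch
    t-tests (unplanned minus other); sex and admission type get
    Yates-corrected chi-square.  Rows with unknown sex are dropped from
    the sex comparison only.
    """
    pos = frame[frame["outcome"] == "unplanned_readmission"]
    neg = frame[frame["outcome"] != "unplanned_readmission"]
    if len(pos) < 2:
        raise ValueError("unplanned-readmission group empty or too small")
    if len(neg) < 2:
        raise ValueError("comparison ('other') group empty or too small")

    out: dict[str, ComparisonResult] = {}
    for col, label in _CONTINUOUS:
        if col not in frame.columns:
            continue
        g1 = GroupSummary(len(pos), float(pos[col].mean()), float(pos[col].std(ddof=1)))
        g2 = GroupSummary(len(neg), float(neg[col].mean()), float(neg[col].std(ddof=1)))
        out[label] = welch_t_from_summary(g1, g2)

    if "sex" in frame.columns:
        known = frame[frame["sex"].isin(["female", "male"])]
        kp = known[known["outcome"] == "unplanned_readmission"]
        kn = known[known["outcome"] != "unplanned_readmission"]
        out["sex"] = chi2_2x2(
            int((kp["sex"] == "female").sum()), int((kp["sex"] == "male").sum()),
            int((kn["sex"] == "female").sum()), int((kn["sex"] == "male").sum()),
        )
    if "admission_type" in frame.columns:
        out["admission_type"] = chi2_2x2(
            int((pos["admission_type"] == "elective").sum()),
            int((pos["admission_type"] == "emergency").sum()),
            int((neg["admission_type"] == "elective").sum()),
            int((neg["admission_type"] == "emergency").sum()),
        )
    return out
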