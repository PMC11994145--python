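"""LACE index scoring.

LACE sums four components — Length of stay (0-7), Acuity of admission
(0 or 3), Comorbidity (0-5, from the CCI), and Emergency-department
visits in the prior 6 months (0 or 4 in the binary default, 0-4 graded)
— into a 0-19 total; a total at or above the threshold (default 10)
flags the admission as high readmission risk.

The L and C bands are the standard published LACE lookup tables and can
be overridden; E is binary by default (any prior ED visit scores 4) with
the standard graded variant (min(count, 4)) as an explicit mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .dictionary import SentimentDictionary
from .extract import CharlsonExtractor

__all__ = [
    "LaceComponents",
    "los_points",
    "acuity_points",
    "comorbidity_points",
    "ed_points",
    "lace_total",
    "LaceScorer",
    "LaceRiskClassifier",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 10

#: (upper bound inclusive, points) bands for length of stay in days.
DEFAULT_L_BANDS: tuple[tuple[float, int], ...] = (
    (0, 0), (1, 1), (2, 2), (3, 3), (6, 4), (13, 5), (float("inf"), 7),
)

#: (upper bound inclusive, points) bands for the comorbidity score.
DEFAULT_C_BANDS: tuple[tuple[float, int], ...] = (
    (0, 0), (1, 1), (2, 2), (3, 3), (float("inf"), 5),
)


def _banded(value: float, bands: Sequence[tuple[float, int]]) -> int:
    for upper, pts in bands:
        if value <= upper:
            return pts
    raise AssertionError("bands must end with an open upper bound")


def los_points(los_days: int, bands: Sequence[tuple[float, int]] = DEFAULT_L_BANDS) -> int:
    """L component: <1 day 0, 1->1, 2->2, 3->3, 4-6->4, 7-13->5, >=14->7."""
    if los_days < 0:
        raise ValueError(f"length of stay must be non-negative, got {los_days}")
    return _banded(los_days, bands)


def acuity_points(admission_type: str) -> int:
    """A component: emergency admission 3, elective 0."""
    if admission_type == "emergency":
        return 3
    if admission_type == "elective":
        return 0
    raise ValueError(f"unknown admission type: {admission_type!r}")


def comorbidity_points(cci: int, bands: Sequence[tuple[float, int]] = DEFAULT_C_BANDS) -> int:
    """C component: CCI 0-3 map through, >=4 caps at 5."""
    if cci < 0:
        raise ValueError(f"comorbidity score must be non-negative, got {cci}")
    return _banded(cci, bands)


def ed_points(ed_visits_6mo: int, mode: str = "binary") -> int:
    """E component.

    ``binary`` (default): no prior ED visit 0, any visit 4.
    ``graded``: min(count, 4), the standard per-visit variant.
    """
    if ed_visits_6mo < 0:
        raise ValueError(f"ED visit count must be non-negative, got {ed_visits_6mo}")
    if mode == "binary":
        return 4 if ed_visits_6mo >= 1 else 0
    if mode == "graded":
        return int(min(ed_visits_6mo, 4))
    raise ValueError(f"unknown ED mode: {mode!r}")


@dataclass(frozen=True)
class LaceComponents:
    """The four LACE sub-scores, their total, and the high-risk flag."""

    l_points: int
    a_points: int
    c_points: int
    e_points: int
    total: int
    high_risk: bool

    def __post_init__(self) -> None:
        if self.total != self.l_points + self.a_points + self.c_points + self.e_points:
            raise ValueError("total must equal the sum of the components")
        if not 0 <= self.total <= 19:
            raise ValueError(f"LACE total out of range [0, 19]: {self.total}")


def lace_total(
    los_days: int,
    admission_type: str,
    cci: int,
    ed_visits_6mo: int,
    *,
    ed_mode: str = "binary",
    threshold: int = DEFAULT_THRESHOLD,
    l_bands: Sequence[tuple[float, int]] = DEFAULT_L_BANDS,
    c_bands: Sequence[tuple[float, int]] = DEFAULT_C_BANDS,
) -> LaceComponents:
    """Compose the four components into a :class:`LaceComponents`."""
    l = los_points(los_days, l_bands)
    a = acuity_points(admission_type)
    c = comorbidity_points(cci, c_bands)
    e = ed_points(ed_visits_6mo, ed_mode)
    total = l + a + c + e
    return LaceComponents(l, a, c, e, total, total >= threshold)


class LaceScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping admission features plus CCI to LACE components.

    Expects a DataFrame with columns ``los_days``, ``admission_type``,
    ``ed_visits_6mo`` and ``cci``; returns a DataFrame with the component
    points, the total and the boolean high-risk flag.
    """

    def __init__(self, ed_mode: str = "binary", threshold: int = DEFAULT_THRESHOLD,
                 l_bands=DEFAULT_L_BANDS, c_bands=DEFAULT_C_BANDS):
        self.ed_mode = ed_mode
        self.threshold = threshold
        self.l_bands = l_bands
        self.c_bands = c_bands

    def fit(self, X=None, y=None) -> "LaceScorer":
        if not 0 <= self.threshold <= 19:
            raise ValueError(f"threshold must lie in [0, 19], got {self.threshold}")
        if self.ed_mode not in ("binary", "graded"):
            raise ValueError(f"unknown ED mode: {self.ed_mode!r}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        required = {"los_days", "admission_type", "ed_visits_6mo", "cci"}
        missing = required - set(X.columns)
        if missing:
            raise KeyError(f"missing required columns: {sorted(missing)}")
        rows = [
            lace_total(
                int(los), adm, int(cci), int(ed),
                ed_mode=self.ed_mode, threshold=self.threshold,
                l_bands=self.l_bands, c_bands=self.c_bands,
            )
            for los, adm, cci, ed in zip(
                X["los_days"], X["admission_type"], X["cci"], X["ed_visits_6mo"]
            )
        ]
        return pd.DataFrame(
            {
                "l_points": [r.l_points for r in rows],
                "a_points": [r.a_points for r in rows],
                "c_points": [r.c_points for r in rows],
                "e_points": [r.e_points for r in rows],
                "lace_total": [r.total for r in rows],
                "high_risk": [r.high_risk for r in rows],
            },
            index=X.index,
        )


class LaceRiskClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end high-risk classifier: text -> CCI -> LACE -> threshold.

    ``predict`` returns 1 where the LACE total is at or above ``threshold``.
    ``decision_function`` returns the LACE total itself, so threshold sweeps
    and sklearn model-selection utilities compose naturally.
    """

    def __init__(
        self,
        dictionary: SentimentDictionary | None = None,
        ed_mode: str = "binary",
        threshold: int = DEFAULT_THRESHOLD,
        negation: bool = False,
    ):
        self.dictionary = dictionary
        self.ed_mode = ed_mode
        self.threshold = threshold
        self.negation = negation

    def fit(self, X=None, y=None) -> "LaceRiskClassifier":
        self.extractor_ = CharlsonExtractor(
            dictionary=self.dictionary, negation=self.negation
        ).fit()
        self.scorer_ = LaceScorer(ed_mode=self.ed_mode, threshold=self.threshold).fit()
        self.classes_ = np.array([0, 1])
        return self

    def _components(self, X: pd.DataFrame) -> pd.DataFrame:
        if "cci" in X.columns:
            frame = X
        else:
            frame = X.assign(cci=self.extractor_.transform(X).ravel())
        return self.scorer_.transform(frame)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self._components(X)["lace_total"].to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold).astype(int)
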