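"""Charlson comorbidity extraction from free-text histories.

The extraction chain is deliberately simple keyword weighting: normalise
the note to tokens, find dictionary surface forms by greedy
longest-phrase-first matching with token consumption, deduplicate
synonyms onto canonical conditions, resolve severity-group dominance,
and add age points (one per completed decade of age past 40).  There is
no negation or family-history handling by default; an optional negation
flag drops matches immediately preceded by a simple negation cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dictionary import (
    DictionaryEntry,
    SentimentDictionary,
    build_default_dictionary,
    normalize_text,
)

__all__ = [
    "normalize_text",
    "match_conditions",
    "age_points",
    "charlson_score",
    "concordance",
    "CharlsonExtractor",
]

#: tokens that, appearing within two tokens before a phrase, negate it
#: when negation handling is enabled.
NEGATION_CUES = frozenset({"no", "not", "without", "denies", "denied", "negative"})


@dataclass(frozen=True)
class _Phrase:
    tokens: tuple[str, ...]
    entry: DictionaryEntry


def _compile_phrases(dictionary: SentimentDictionary) -> dict[str, list[_Phrase]]:
    """Index phrases by first token; each bucket sorted longest first,
    ties broken by higher weight (so e.g. a graded variant wins)."""
    index: dict[str, list[_Phrase]] = {}
    for entry in dictionary:
        for nf in entry.normalized_forms:
            index.setdefault(nf[0], []).append(_Phrase(nf, entry))
    for bucket in index.values():
        bucket.sort(key=lambda p: (-len(p.tokens), -p.entry.weight))
    return index


def _occurrences(tokens: Sequence[str], index: Mapping[str, list[_Phrase]]):
    """All (start, phrase) occurrences of dictionary phrases in ``tokens``.

    Matching is exact on whole tokens, so abbreviations ("DM", "CA") never
    fire inside longer words.
    """
    n = len(tokens)
    for i, tok in enumerate(tokens):
        for ph in index.get(tok, ()):
            k = len(ph.tokens)
            if i + k <= n and tuple(tokens[i : i + k]) == ph.tokens:
                yield i, ph


def match_conditions(
    tokens: Sequence[str],
    dictionary: SentimentDictionary,
    *,
    negation: bool = False,
    _index: Mapping[str, list[_Phrase]] | None = None,
) -> dict[str, int]:
    """Match dictionary conditions in a token sequence.

    Greedy longest-phrase-first with token consumption: occurrences are
    ranked by (length desc, weight desc, position) and accepted only if
    none of their tokens was consumed by an earlier-accepted longer
    phrase, so "metastatic solid ca" blocks a separate "ca" match on the
    same tokens.  Each canonical condition appears at most once, and
    within a severity group only the highest-weight matched condition is
    retained.

    Returns a mapping canonical_condition -> weight.
    """
    index = _index if _index is not None else _compile_phrases(dictionary)
    occ = sorted(
        _occurrences(tokens, index),
        key=lambda sp: (-len(sp[1].tokens), -sp[1].entry.weight, sp[0]),
    )
    consumed = np.zeros(len(tokens), dtype=bool)
    matched: dict[str, DictionaryEntry] = {}
    for start, ph in occ:
        span = slice(start, start + len(ph.tokens))
        if consumed[span].any():
            continue
        if negation and _is_negated(tokens, start):
            continue
        consumed[span] = True
        matched.setdefault(ph.entry.canonical_condition, ph.entry)

    # severity-group dominance
    by_group: dict[str, DictionaryEntry] = {}
    for e in matched.values():
        key = e.severity_group if e.severity_group is not None else e.canonical_condition
        prev = by_group.get(key)
        if prev is None or (e.weight, e.canonical_condition) > (
            prev.weight,
            prev.canonical_condition,
        ):
            by_group[key] = e
    return {e.canonical_condition: e.weight for e in by_group.values()}


def _is_negated(tokens: Sequence[str], start: int) -> bool:
    lo = max(0, start - 2)
    return any(t in NEGATION_CUES for t in tokens[lo:start])


def age_points(age: float) -> int:
    """Charlson age adjustment: one point per completed decade past 40.

    0 for age <= 40 (more precisely, for age < 50); 50-59 -> 1,
    60-69 -> 2, 70-79 -> 3, and so on.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age <= 40:
        return 0
    return int(math.floor((age - 40) / 10))


def charlson_score(
    record,
    dictionary: SentimentDictionary | None = None,
    *,
    negation: bool = False,
) -> int:
    """CCI for one admission: matched condition weights plus age points.

    ``record`` needs ``history_text`` and ``age`` attributes (a
    PatientRecord, a dataclass, or a pandas row via attribute access).
    """
    if dictionary is None:
        dictionary = build_default_dictionary()
    tokens = normalize_text(record.history_text or "")
    weights = match_conditions(tokens, dictionary, negation=negation)
    return sum(weights.values()) + age_points(float(record.age))


def concordance(scores_a: Sequence[int], scores_b: Sequence[int]) -> float:
    """Fraction of positions at which two score sequences agree exactly.

    Used to compare machine-extracted comorbidity scores against a gold or
    expert-reviewed series.
    """
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if a.size == 0:
        raise ValueError("concordance undefined for empty sequences")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(a == b))


class CharlsonExtractor(BaseEstimator, TransformerMixin):
    """Transformer computing the CCI from free-text history plus age.

    Parameters
    ----------
    dictionary : SentimentDictionary, optional
        Weighted keyword dictionary; the built-in default when None.
    negation : bool, default False
        Drop matches immediately preceded by a simple negation cue
        ("no DM" would then not score).  Off by default: the baseline
        procedure is pure keyword weighting.

    After ``fit``, ``dictionary_`` holds the dictionary in use and
    ``transform`` maps a DataFrame with ``history_text`` and ``age``
    columns to an (n, 1) integer array of CCI scores.
    """

    def __init__(self, dictionary: SentimentDictionary | None = None,
                 negation: bool = False):
        self.dictionary = dictionary
        self.negation = negation

    def fit(self, X=None, y=None) -> "CharlsonExtractor":
        self.dictionary_ = (
            self.dictionary if self.dictionary is not None
            else build_default_dictionary()
        )
        self._index_ = _compile_phrases(self.dictionary_)
        return self

    def score_text(self, text: str, age: float) -> int:
        """CCI for a single history string at a given age."""
        tokens = normalize_text(text or "")
        weights = match_conditions(
            tokens, self.dictionary_, negation=self.negation, _index=self._index_
        )
        return sum(weights.values()) + age_points(float(age))

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "dictionary_"):
            raise RuntimeError("CharlsonExtractor is not fitted; call fit() first")
        if not {"history_text", "age"}.issubset(X.columns):
            missing = {"history_text", "age"} - set(X.columns)
            raise KeyError(f"missing required columns: {sorted(missing)}")
        texts = X["history_text"].fillna("").to_numpy()
        ages = X["age"].to_numpy(dtype=float)
        out = np.fromiter(
            (self.score_text(t, a) for t, a in zip(texts, ages)),
            dtype=np.int64,
            count=len(texts),
        )
        return out.reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["cci"], dtype=object)


def extract_cci(
    frame: pd.DataFrame,
    dictionary: SentimentDictionary | None = None,
    *,
    negation: bool = False,
) -> np.ndarray:
    """Functional convenience wrapper over :class:`CharlsonExtractor`."""
    est = CharlsonExtractor(dictionary=dictionary, negation=negation).fit()
    return est.transform(frame).ravel()
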