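"""Weighted comorbidity keyword dictionary.

The Charlson Comorbidity Index (CCI) assigns integer weights (1, 2, 3 or 6)
to chronic conditions.  In registries where comorbidity lives only in the
free-text "history of health complaints", the CCI can be recovered by
matching a curated dictionary of condition surface forms (full names and
the abbreviations clinicians actually write: "DM", "COPD", "CCF", ...)
against the note and summing the weights of the distinct conditions found.

This module defines that dictionary: entries, validation, severity-group
dominance (e.g. severe liver disease supersedes cirrhosis; metastatic
disease supersedes a plain malignancy mention), and JSON (de)serialisation.
Text normalisation and matching live in :mod:`lacerisk.extract`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "DictionaryEntry",
    "SentimentDictionary",
    "build_default_dictionary",
    "normalize_text",
    "VALID_WEIGHTS",
]

VALID_WEIGHTS = frozenset({1, 2, 3, 6})

# Unicode hyphen/dash variants collapsed to ASCII "-" before tokenising.
_DASHES = str.maketrans({c: "-" for c in "‐‑‒–—−"})
_NON_TOKEN = re.compile(r"[^a-z0-9/-]+")


def normalize_text(raw: str) -> list[str]:
    """Normalise free text to a token sequence.

    Lower-cases, maps unicode dashes to "-", replaces all punctuation except
    intra-token "/" and "-" with whitespace, and splits.  "/" and "-" are
    kept so surface forms such as "CA w/o mets" and "moderate-severe CKD"
    survive as matchable tokens.  Deterministic; empty input gives [].
    """
    if not raw:
        return []
    s = raw.lower().translate(_DASHES)
    s = _NON_TOKEN.sub(" ", s)
    # drop tokens that are pure separator residue ("-", "/", "-/-")
    return [t for t in s.split() if t.strip("/-")]


@dataclass(frozen=True)
class DictionaryEntry:
    """One canonical comorbid condition with its surface forms and weight.

    ``severity_group`` links graded variants of one organ system (e.g. the
    liver group at weights 1 and 3, the malignancy group at 2 and 6); during
    matching only the highest-weight matched entry of a group is retained.
    """

    canonical_condition: str
    surface_forms: tuple[str, ...]
    weight: int
    severity_group: str | None = None

    def __post_init__(self) -> None:
        if self.weight not in VALID_WEIGHTS:
            raise ValueError(
                f"{self.canonical_condition}: weight {self.weight} not in "
                f"{sorted(VALID_WEIGHTS)}"
            )
        if not self.surface_forms:
            raise ValueError(f"{self.canonical_condition}: no surface forms")
        for form in self.surface_forms:
            if not normalize_text(form):
                raise ValueError(
                    f"{self.canonical_condition}: surface form {form!r} "
                    "normalises to nothing"
                )

    @property
    def normalized_forms(self) -> list[tuple[str, ...]]:
        return [tuple(normalize_text(f)) for f in self.surface_forms]


@dataclass
class SentimentDictionary:
    """A versioned collection of :class:`DictionaryEntry`.

    Invariant: no two entries share an identical normalised surface form.
    """

    entries: list[DictionaryEntry] = field(default_factory=list)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: dict[tuple[str, ...], str] = {}
        for e in self.entries:
            for nf in e.normalized_forms:
                if nf in seen and seen[nf] != e.canonical_condition:
                    raise ValueError(
                        f"surface form {' '.join(nf)!r} appears under both "
                        f"{seen[nf]!r} and {e.canonical_condition!r}"
                    )
                seen[nf] = e.canonical_condition

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, surface_form: str) -> DictionaryEntry:
        """Return the entry owning ``surface_form`` (normalised comparison)."""
        target = tuple(normalize_text(surface_form))
        for e in self.entries:
            if target in e.normalized_forms:
                return e
        raise KeyError(surface_form)

    def by_canonical(self, name: str) -> DictionaryEntry:
        for e in self.entries:
            if e.canonical_condition == name:
                return e
        raise KeyError(name)

    @property
    def canonical_conditions(self) -> list[str]:
        return [e.canonical_condition for e in self.entries]

    def score_conditions(self, conditions: Iterable[str]) -> int:
        """Sum the weights of a set of canonical conditions.

        Applies the same deduplication and severity-group dominance as the
        text matcher: each canonical condition counts once, and within a
        severity group only the highest weight contributes.  This is the
        shared scoring rule used both by extraction and by the synthetic
        generator's gold scores.
        """
        chosen: dict[str, DictionaryEntry] = {}
        for name in set(conditions):
            e = self.by_canonical(name)
            key = e.severity_group if e.severity_group is not None else e.canonical_condition
            prev = chosen.get(key)
            if prev is None or (e.weight, e.canonical_condition) > (
                prev.weight,
                prev.canonical_condition,
            ):
                chosen[key] = e
        return sum(e.weight for e in chosen.values())

    # -- serialisation -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": self.version,
            "entries": [
                {
                    "canonical_condition": e.canonical_condition,
                    "surface_forms": list(e.surface_forms),
                    "weight": e.weight,
                    "severity_group": e.severity_group,
                }
                for e in self.entries
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SentimentDictionary":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        entries = [
            DictionaryEntry(
                canonical_condition=d["canonical_condition"],
                surface_forms=tuple(d["surface_forms"]),
                weight=int(d["weight"]),
                severity_group=d.get("severity_group"),
            )
            for d in payload["entries"]
        ]
        return cls(entries=entries, version=payload.get("version", "unversioned"))


def build_default_dictionary() -> SentimentDictionary:
    """Build the default weighted comorbidity dictionary.

    Surface variants of one clinical concept (e.g. "DM"/"diabetes",
    "stroke"/"CVA"/"TIA", "CHF"/"CCF"/"congestive cardiac failure") share a
    canonical condition so a Charlson category is scored once per patient no
    matter how many synonyms the note contains.  The liver and malignancy
    groups carry graded weights resolved by severity dominance.
    """
    E = DictionaryEntry
    entries = [
        # weight 1 -----------------------------------------------------
        E("myocardial_infarction", ("myocardial infarction",), 1),
        E(
            "heart_failure",
            ("CHF", "CFF", "CCF", "congestive cardiac failure",
             "congestive heart failure"),
            1,
        ),
        E(
            "peripheral_vascular_disease",
            ("PVD", "peripheral vascular disease", "gangrene",
             "acute ischemia", "aneurysm"),
            1,
        ),
        E(
            "cerebrovascular_disease",
            ("CVA", "CVD", "stroke", "TIA", "transient ischemic attack",
             "transient ischemic attacks", "cerebrovascular accident"),
            1,
        ),
        E("dementia", ("dementia",), 1),
        E(
            "chronic_pulmonary_disease",
            ("COPD", "OAD", "obstructive airways disease", "emphysema",
             "chronic obstructive pulmonary disease"),
            1,
        ),
        E("peptic_ulcer_disease", ("PUD", "peptic ulcer disease"), 1),
        E(
            "mild_liver_disease",
            ("mild liver disease", "cirrhosis", "hepatitis"),
            1,
            severity_group="liver",
        ),
        E(
            "coronary_artery_disease",
            ("coronary artery disease", "CAD", "angina",
             "coronary angioplasty", "bypass surgery", "stenting"),
            1,
        ),
        # weight 2 -----------------------------------------------------
        E(
            "renal_disease",
            ("moderate-severe CKD", "ESRD", "end stage renal disease",
             "renal disease"),
            2,
        ),
        E(
            "leukemia",
            ("CLL", "chronic lymphocytic leukemia", "leukemia"),
            2,
        ),
        E(
            "malignancy",
            ("CA w/o mets", "MASS nonmalignant", "carcinoma", "CA", "mass",
             "carcinoma malignant"),
            2,
            severity_group="malignancy",
        ),
        E(
            "diabetes",
            ("DM with end-organ damage", "diabetes with retinopathy",
             "diabetes with nephropathy", "diabetes with neuropathy",
             "diabetic foot", "DM", "diabetes", "diabetes with amputation",
             "diabetic amputation"),
            2,
        ),
        # weight 3 -----------------------------------------------------
        E(
            "moderate_severe_liver_disease",
            ("moderate liver disease", "severe liver disease", "jaundice"),
            3,
            severity_group="liver",
        ),
        # weight 6 -----------------------------------------------------
        E(
            "metastatic_solid_tumor",
            ("metastatic solid CA", "metastatic solid carcinoma"),
            6,
            severity_group="malignancy",
        ),
        E("aids", ("AIDS",), 6),
    ]
    return SentimentDictionary(entries=entries, version="cci-dictionary-1")
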