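"""Patient admission records: schema, reading, filtering, writing.

One row per admission with the fields the pipeline needs: demographics,
the LACE inputs (length of stay, admission acuity, prior ED visits),
the free-text history of health complaints, and the 30-day outcome
("unplanned_readmission" vs "other", where other pools planned
readmissions and patients not readmitted).  Synthetic records carry an
optional ``gold_cci`` ground-truth comorbidity score.

Supported formats: CSV (RFC 4180, header required) and JSON-lines, both
UTF-8, with a case-insensitive header match.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lace import LaceComponents

__all__ = [
    "PatientRecord",
    "SchemaError",
    "RowParseError",
    "read_cohort",
    "apply_eligibility_filter",
    "write_scored",
    "records_to_frame",
    "frame_to_records",
    "REQUIRED_COLUMNS",
    "AGE_MIN",
    "AGE_MAX",
]

REQUIRED_COLUMNS = (
    "patient_id", "cohort", "age", "sex", "admission_type",
    "los_days", "ed_visits_6mo", "history_text", "outcome",
)
AGE_MIN, AGE_MAX = 18.0, 100.0

_SEX_ALIASES = {"f": "female", "female": "female", "m": "male", "male": "male"}
_ADMISSION_VALUES = {"elective", "emergency"}
_OUTCOME_ALIASES = {
    "unplanned_readmission": "unplanned_readmission",
    "unplanned": "unplanned_readmission",
    "other": "other",
}


class SchemaError(ValueError):
    """The file header/keys do not match the documented schema."""


class RowParseError(ValueError):
    """A row's value could not be parsed; carries the row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass
class PatientRecord:
    """One admission."""

    patient_id: str
    cohort: str                 # trauma | general
    age: float
    sex: str                    # female | male | unknown
    admission_type: str         # elective | emergency
    los_days: int
    ed_visits_6mo: int
    history_text: str
    outcome: str                # unplanned_readmission | other
    gold_cci: int | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"{self.patient_id}: age must be non-negative")
        if self.los_days < 0 or self.ed_visits_6mo < 0:
            raise ValueError(f"{self.patient_id}: counts must be non-negative")
        if self.gold_cci is not None and self.gold_cci < 0:
            raise ValueError(f"{self.patient_id}: gold_cci must be non-negative")


def _normalize_sex(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    return _SEX_ALIASES.get(str(value).strip().lower(), "unknown")


def _parse_row(i: int, row: dict) -> PatientRecord:
    try:
        age = float(row["age"])
    except (TypeError, ValueError):
        raise RowParseError(i, f"non-numeric age: {row['age']!r}") from None
    try:
        los = int(float(row["los_days"]))
        ed = int(float(row["ed_visits_6mo"]))
    except (TypeError, ValueError):
        raise RowParseError(
            i, f"non-numeric los_days/ed_visits_6mo: "
               f"{row['los_days']!r}/{row['ed_visits_6mo']!r}") from None

    adm = str(row["admission_type"]).strip().lower()
    if adm not in _ADMISSION_VALUES:
        raise RowParseError(i, f"unknown admission_type: {row['admission_type']!r}")
    outcome_raw = str(row["outcome"]).strip().lower()
    if outcome_raw not in _OUTCOME_ALIASES:
        raise RowParseError(i, f"unknown outcome: {row['outcome']!r}")

    gold = row.get("gold_cci")
    if gold is None or (isinstance(gold, float) and np.isnan(gold)) or gold == "":
        gold_cci = None
    else:
        gold_cci = int(float(gold))

    history = row.get("history_text")
    if history is None or (isinstance(history, float) and np.isnan(history)):
        history = ""

    return PatientRecord(
        patient_id=str(row["patient_id"]),
        cohort=str(row["cohort"]).strip().lower(),
        age=age,
        sex=_normalize_sex(row["sex"]),
        admission_type=adm,
        los_days=los,
        ed_visits_6mo=ed,
        history_text=str(history),
        outcome=_OUTCOME_ALIASES[outcome_raw],
        gold_cci=gold_cci,
    )


def _load_frame(path: str | Path, format: str | None) -> pd.DataFrame:
    p = Path(path)
    if format is None:
        format = "jsonl" if p.suffix in {".jsonl", ".ndjson", ".json"} else "csv"
    if format == "csv":
        frame = pd.read_csv(p, dtype={"patient_id": str})
    elif format == "jsonl":
        frame = pd.read_json(p, orient="records", lines=True,
                             dtype={"patient_id": str})
    else:
        raise ValueError(f"unknown format: {format!r}")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    return frame


def read_cohort(path: str | Path, format: str | None = None) -> list[PatientRecord]:
    """Read admission records from CSV or JSON-lines, preserving row order.

    Raises :class:`SchemaError` naming any missing required column and
    :class:`RowParseError` (with the 0-based row index) for unparseable
    values.  Unrecognised sex values become "unknown"; unrecognised
    admission types or outcomes are errors.
    """
    frame = _load_frame(path, format)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return [_parse_row(i, row) for i, row in enumerate(frame.to_dict("records"))]


def apply_eligibility_filter(
    records: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], int]:
    """Keep admissions with age in [18, 100] inclusive; order preserved.

    Returns (kept, n_excluded).  Both bounds are inclusive: the exclusion
    rule removes patients younger than 18 or older than 100.
    """
    kept = [r for r in records if AGE_MIN <= r.age <= AGE_MAX]
    return kept, len(records) - len(kept)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Records as a DataFrame in schema column order."""
    cols = [f.name for f in dc_fields(PatientRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    return [_parse_row(i, row) for i, row in enumerate(frame.to_dict("records"))]


_SCORE_COLUMNS = ("cci", "l_points", "a_points", "c_points", "e_points",
                  "lace_total", "high_risk_flag")


def write_scored(
    records: Sequence[PatientRecord],
    scores: Sequence[LaceComponents],
    path: str | Path,
    format: str = "csv",
    cci: Sequence[int] | None = None,
) -> None:
    """Write records with their LACE components appended, aligned by order.

    Adds cci, l/a/c/e points, lace_total and high_risk_flag columns.  The
    CCI column defaults to each score's C-relevant input being unavailable
    here, so pass ``cci`` explicitly (the extractor output); if omitted,
    the record's ``gold_cci`` is used when present.
    """
    if len(records) != len(scores):
        raise ValueError(
            f"records/scores length mismatch: {len(records)} vs {len(scores)}"
        )
    if cci is not None and len(cci) != len(records):
        raise ValueError("cci length does not match records")

    frame = records_to_frame(records)
    if cci is not None:
        frame["cci"] = list(cci)
    else:
        frame["cci"] = [r.gold_cci if r.gold_cci is not None else 0 for r in records]
    frame["l_points"] = [s.l_points for s in scores]
    frame["a_points"] = [s.a_points for s in scores]
    frame["c_points"] = [s.c_points for s in scores]
    frame["e_points"] = [s.e_points for s in scores]
    frame["lace_total"] = [s.total for s in scores]
    frame["high_risk_flag"] = [s.high_risk for s in scores]

    p = Path(path)
    if format == "csv":
        frame.to_csv(p, index=False)
    elif format == "jsonl":
        frame.to_json(p, orient="records", lines=True)
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_scored(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a scored-records file back as a DataFrame."""
    frame = _load_frame(path, format)
    missing = [c for c in (*REQUIRED_COLUMNS, *_SCORE_COLUMNS)
               if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return frame
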