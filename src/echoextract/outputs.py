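"""Serialisation of extraction results to long and wide tabular forms.

The long form (one row per report × outcome) is the evaluation atom; the
wide form (one row per report, one column per canonical outcome) is the
database-facing layout. Absent extractions serialise as empty cells, never
zeros — the false-negative / true-negative distinction downstream depends
on it. CSV dialect: UTF-8, comma delimiter, quoted free-text fields, "."
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .rules import OutcomeAnnotation

LONG_COLUMNS = [
    "report_id", "outcome", "value", "unit", "ordinal_label", "negated",
    "context", "provenance", "rule_name",
]


class IntegrityError(ValueError):
    """Raised when records violate the one-row-per-(report, outcome) contract."""


@dataclass(frozen=True)
class ExtractionRecord:
    """One resolved (report, outcome, value) row."""

    report_id: str
    outcome: str
    value: float
    unit: str = ""
    ordinal_label: Optional[str] = None
    negated: bool = False
    context: str = ""
    provenance: str = ""
    rule_name: str = ""


def records_from_annotations(report_id: str,
                             annotations: Sequence[OutcomeAnnotation]
                             ) -> list[ExtractionRecord]:
    """Primary (non-suppressed) annotations of one report as records."""
    return [
        ExtractionRecord(
            report_id=report_id,
            outcome=a.outcome,
            value=a.var_value,
            unit=a.unit,
            ordinal_label=a.label,
            negated=a.negated,
            context=a.context or "",
            provenance=a.matched_text,
            rule_name=a.rule_name,
        )
        for a in annotations if not a.suppressed
    ]


def to_long(records: Sequence[ExtractionRecord]) -> pd.DataFrame:
    """Long table: one row per record, stable column order.

    Duplicate (report_id, outcome) pairs raise :class:`IntegrityError`.
    """
    rows = [
        {
            "report_id": r.report_id,
            "outcome": r.outcome,
            "value": r.value,
            "unit": r.unit,
            "ordinal_label": "" if r.ordinal_label is None else r.ordinal_label,
            "negated": bool(r.negated),
            "context": r.context,
            "provenance": r.provenance,
            "rule_name": r.rule_name,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    dup = df.duplicated(subset=["report_id", "outcome"])
    if dup.any():
        pairs = df.loc[dup, ["report_id", "outcome"]].values.tolist()
        raise IntegrityError(f"duplicate (report_id, outcome) rows: {pairs}")
    return df


def to_wide(records: Sequence[ExtractionRecord],
            lexicon: Lexicon) -> pd.DataFrame:
    """Wide table: one row per report, one value column per canonical outcome.

    Absent outcomes are empty (NaN) cells, never zeros.
    """
    long = to_long(records)
    outcome_cols = [o.canonical_name for o in lexicon]
    report_ids = list(dict.fromkeys(long["report_id"]))
    wide = long.pivot(index="report_id", columns="outcome", values="value")
    wide = wide.reindex(index=report_ids, columns=outcome_cols)
    wide.insert(0, "report_id", wide.index)
    return wide.reset_index(drop=True).rename_axis(columns=None)


def from_wide(wide: pd.DataFrame, lexicon: Lexicon) -> list[ExtractionRecord]:
    """Inverse of :func:`to_wide` for value, unit and ordinal code.

    Provenance fields are not representable in the wide layout, so the
    round trip is lossless for value, canonical unit and ordinal
    code/label only.
    """
    records: list[ExtractionRecord] = []
    for _, row in wide.iterrows():
        for outcome in lexicon:
            name = outcome.canonical_name
            if name not in wide.columns:
                continue
            value = row[name]
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            label = None
            if outcome.is_discrete:
                label = outcome.severity_scale.code_to_label(int(value))
            records.append(ExtractionRecord(
                report_id=str(row["report_id"]),
                outcome=name,
                value=float(value),
                unit=outcome.canonical_unit or "",
                ordinal_label=label,
            ))
    return records


def write_long_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def read_long_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, encoding="utf-8",
        dtype={"report_id": str, "outcome": str},
        keep_default_na=False, na_values=[""],
    )
    missing = [c for c in ("report_id", "outcome", "value") if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing required columns {missing}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df
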