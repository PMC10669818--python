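"""Validation metrics for extraction systems against a reference standard.

Two tracks, matching the two data types the extractor emits:

* **Continuous** outcomes are judged as an inter-rater agreement problem:
  coefficient of determination R² (squared Pearson correlation of the
  paired values) and the intraclass correlation coefficient ICC(2,1) —
  two-way random effects, absolute agreement, single measure — with the
  conventional reliability bands (poor < 0.5, moderate 0.5–0.75, good
  0.75–0.9, excellent > 0.9). The two statistics are deliberately
  complementary: a system that extracts the right number on the wrong unit
  scale keeps R² = 1 while ICC collapses, because absolute agreement
  penalises the scale offset.

* **Discrete** outcomes are judged as presence-plus-category
  classification: per-outcome TP/FN/FP/TN tallies, precision, recall and
  F1, with rare outcomes aggregated so the ratios stay defined, and a
  pooled accuracy over all evaluated instances.

Per (report, outcome) instance: TP if both sides assert the same category;
FP if the system asserts where the reference is silent *or* asserts the
wrong category; FN if the reference asserts and the system is silent; TN if
both are silent. Each instance lands in exactly one cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: reliability bands for ICC values
ICC_BANDS = (
    (0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (float("inf"), "excellent"),
)


class UndefinedMetric(ValueError):
    """Signals a metric with an undefined value (zero denominator)."""


def icc_band(value: float) -> str:
    for upper, band in ICC_BANDS:
        if value < upper:
            return band
    return "excellent"


# ---------------------------------------------------------------------------
# continuous track
# ---------------------------------------------------------------------------


@dataclass
class PairedSeries:
    """Aligned (reference, system) value vectors for one continuous outcome."""

    outcome: str
    reference: np.ndarray
    system: np.ndarray

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.system = np.asarray(self.system, dtype=float)
        if self.reference.shape != self.system.shape:
            raise ValueError("reference and system vectors must align")

    def complete(self) -> tuple[np.ndarray, np.ndarray]:
        mask = ~(np.isnan(self.reference) | np.isnan(self.system))
        return self.reference[mask], self.system[mask]


def paired_series(system: pd.DataFrame, reference: pd.DataFrame,
                  outcome: str) -> PairedSeries:
    """Build a PairedSeries from two long tables, aligned on report_id.

    Reports present on either side are included; a missing side is NaN.
    """
    sys_vals = (system[system["outcome"] == outcome]
                .set_index("report_id")["value"])
    ref_vals = (reference[reference["outcome"] == outcome]
                .set_index("report_id")["value"])
    ids = sorted(set(sys_vals.index) | set(ref_vals.index))
    return PairedSeries(
        outcome=outcome,
        reference=ref_vals.reindex(ids).to_numpy(dtype=float),
        system=sys_vals.reindex(ids).to_numpy(dtype=float),
    )


def r_squared(series: PairedSeries) -> float:
    """Coefficient of determination: squared Pearson r of complete pairs.

    Raises :class:`UndefinedMetric` with fewer than two complete pairs or
    zero variance on either side.
    """
    ref, sys_ = series.complete()
    if len(ref) < 2:
        raise UndefinedMetric(f"{series.outcome}: need >= 2 complete pairs")
    if np.std(ref) == 0 or np.std(sys_) == 0:
        raise UndefinedMetric(f"{series.outcome}: zero variance")
    r = stats.pearsonr(ref, sys_).statistic
    return float(r * r)


def icc(series: PairedSeries) -> tuple[float, float, str]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares over the n × 2
    (subject × rater) table of complete pairs:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns (icc, one-sided F-test p-value, reliability band). A degenerate
    table in which every cell is identical has perfect agreement by
    convention: ICC = 1, p = NaN.
    """
    ref, sys_ = series.complete()
    n = len(ref)
    if n < 2:
        raise UndefinedMetric(f"{series.outcome}: need >= 2 complete pairs")
    data = np.column_stack([ref, sys_])  # n subjects x k raters
    k = 2
    grand = data.mean()
    if np.all(data == data.flat[0]):
        return 1.0, float("nan"), "excellent"
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = float((msr - mse) / denom) if denom != 0 else 1.0
    if mse == 0:
        p = 0.0 if msr > 0 else float("nan")
    else:
        f_obs = msr / mse
        p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
    return value, p, icc_band(value)


def bubble_data(system: pd.DataFrame, reference: pd.DataFrame,
                outcomes: Sequence[str]) -> pd.DataFrame:
    """Magnitude-calibration data for a bubble plot.

    Per continuous outcome: x = total reference magnitude, y = total system
    magnitude, size = how often the system extracted the outcome. A
    well-calibrated system sits on the x = y diagonal; under-extraction
    falls below it.
    """
    rows = []
    for outcome in outcomes:
        ref_vals = reference.loc[reference["outcome"] == outcome, "value"]
        sys_vals = system.loc[system["outcome"] == outcome, "value"]
        rows.append({
            "outcome": outcome,
            "reference_magnitude": float(ref_vals.abs().sum()),
            "system_magnitude": float(sys_vals.abs().sum()),
            "frequency": int(sys_vals.notna().sum()),
        })
    return pd.DataFrame(rows, columns=[
        "outcome", "reference_magnitude", "system_magnitude", "frequency",
    ])


# ---------------------------------------------------------------------------
# discrete track
# ---------------------------------------------------------------------------


@dataclass
class DiscreteTally:
    """Per-outcome confusion counts for presence + category evaluation."""

    outcome: str
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "DiscreteTally") -> "DiscreteTally":
        return DiscreteTally(
            outcome=f"{self.outcome} + {other.outcome}",
            tp=self.tp + other.tp, fn=self.fn + other.fn,
            fp=self.fp + other.fp, tn=self.tn + other.tn,
        )


def tally_discrete(system: pd.DataFrame, reference: pd.DataFrame,
                   outcome: str,
                   report_ids: Optional[Sequence[str]] = None) -> DiscreteTally:
    """Tally one discrete outcome over a report universe.

    ``report_ids`` defines the evaluated universe (defaults to the union of
    report ids appearing anywhere in either table, so reports in which
    neither side asserts this outcome still count as true negatives).
    A present-but-wrong-category assertion counts as one false positive;
    no instance is double-counted.
    """
    if report_ids is None:
        report_ids = sorted(set(system["report_id"]) | set(reference["report_id"]))
    if not report_ids:
        raise UndefinedMetric("empty report universe")
    sys_codes = (system[system["outcome"] == outcome]
                 .set_index("report_id")["value"].to_dict())
    ref_codes = (reference[reference["outcome"] == outcome]
                 .set_index("report_id")["value"].to_dict())
    tally = DiscreteTally(outcome=outcome)
    for rid in report_ids:
        s, r = sys_codes.get(rid), ref_codes.get(rid)
        s = None if s is not None and math.isnan(s) else s
        r = None if r is not None and math.isnan(r) else r
        if s is None and r is None:
            tally.tn += 1
        elif s is None:
            tally.fn += 1
        elif r is None:
            tally.fp += 1
        elif int(s) == int(r):
            tally.tp += 1
        else:
            tally.fp += 1
    assert tally.total == len(report_ids)
    return tally


def precision_recall_f1(tally: DiscreteTally) -> tuple[float, float, float]:
    """Precision, recall and F1 from one tally, rounded to 2 decimals.

    Undefined ratios (zero denominators) raise :class:`UndefinedMetric`
    rather than returning 0 — aggregate rare outcomes first.
    """
    if tally.tp + tally.fp == 0 or tally.tp + tally.fn == 0:
        raise UndefinedMetric(
            f"{tally.outcome}: precision/recall undefined for tally "
            f"({tally.tp},{tally.fn},{tally.fp},{tally.tn})"
        )
    precision = tally.tp / (tally.tp + tally.fp)
    recall = tally.tp / (tally.tp + tally.fn)
    f1 = 2 * precision * recall / (precision + recall)
    return round(precision, 2), round(recall, 2), round(f1, 2)


def aggregate_rare(tallies: Sequence[DiscreteTally],
                   label: Optional[str] = None) -> DiscreteTally:
    """Cell-wise sum of tallies under a combined label.

    Used for outcomes too rare to support defined precision/recall on
    their own.
    """
    if not tallies:
        raise UndefinedMetric("nothing to aggregate")
    out = DiscreteTally(
        outcome=label or " + ".join(t.outcome for t in tallies),
        tp=sum(t.tp for t in tallies), fn=sum(t.fn for t in tallies),
        fp=sum(t.fp for t in tallies), tn=sum(t.tn for t in tallies),
    )
    return out


def pooled_accuracy(tallies: Sequence[DiscreteTally]
                    ) -> tuple[float, float, float, int]:
    """Pooled confusion-matrix accuracy over all tallies.

    Returns (accuracy %, FN % of total, FP % of total, total instances),
    percentages rounded to 2 decimals.
    """
    total = sum(t.total for t in tallies)
    if total == 0:
        raise UndefinedMetric("no evaluated instances")
    correct = sum(t.tp + t.tn for t in tallies)
    fn = sum(t.fn for t in tallies)
    fp = sum(t.fp for t in tallies)
    return (
        round(100.0 * correct / total, 2),
        round(100.0 * fn / total, 2),
        round(100.0 * fp / total, 2),
        total,
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def evaluate_tables(system: pd.DataFrame, reference: pd.DataFrame,
                    lexicon,
                    report_ids: Optional[Sequence[str]] = None,
                    aggregate_stenosis: bool = True
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full dual-track evaluation of a system table against a reference.

    Returns (continuous agreement table, discrete metric table, pooled
    summary dict). Stenosis outcomes are aggregated across valves by
    default, the standard treatment for rare categories.
    """
    if report_ids is None:
        report_ids = sorted(set(system["report_id"]) | set(reference["report_id"]))
    if not report_ids:
        raise UndefinedMetric("system and reference share no report ids")

    cont_rows = []
    for outcome in lexicon.continuous:
        name = outcome.canonical_name
        series = paired_series(system, reference, name)
        row = {"outcome": name, "n_pairs": int(len(series.complete()[0]))}
        try:
            row["r_squared"] = round(r_squared(series), 2)
        except UndefinedMetric:
            row["r_squared"] = float("nan")
        try:
            value, p, band = icc(series)
            row.update(icc=round(value, 2), icc_p=round(p, 4), band=band)
        except UndefinedMetric:
            row.update(icc=float("nan"), icc_p=float("nan"), band="")
        cont_rows.append(row)
    continuous = pd.DataFrame(
        cont_rows, columns=["outcome", "n_pairs", "r_squared", "icc",
                            "icc_p", "band"])

    tallies: list[DiscreteTally] = []
    stenosis: list[DiscreteTally] = []
    for outcome in lexicon.discrete:
        tally = tally_discrete(system, reference, outcome.canonical_name,
                               report_ids)
        if aggregate_stenosis and "Stenosis" in outcome.canonical_name:
            stenosis.append(tally)
        else:
            tallies.append(tally)
    if stenosis:
        tallies.append(aggregate_rare(stenosis))

    disc_rows = []
    for tally in tallies:
        row = {"outcome": tally.outcome, "TP": tally.tp, "FN": tally.fn,
               "FP": tally.fp, "TN": tally.tn}
        try:
            row["precision"], row["recall"], row["f1"] = precision_recall_f1(tally)
        except UndefinedMetric:
            row["precision"] = row["recall"] = row["f1"] = float("nan")
        disc_rows.append(row)
    discrete = pd.DataFrame(
        disc_rows, columns=["outcome", "TP", "FN", "FP", "TN",
                            "precision", "recall", "f1"])

    accuracy, fn_pct, fp_pct, total = pooled_accuracy(tallies)
    summary = {"accuracy_pct": accuracy, "fn_pct": fn_pct,
               "fp_pct": fp_pct, "total_instances": total}
    return continuous, discrete, summary
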