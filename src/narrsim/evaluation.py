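"""Confusion-based metrics, subgroup stratification and learning curves.

Conventions for degenerate cells (a model predicting a single class at a
tiny training budget) are fixed here: precision, recall and F1 are 0 when
their denominators are 0, and the false negative rate (FNR) is 0 when no
true positives exist.  Whenever any positive cases exist,
``recall + fnr == 1`` and this is asserted on every emitted row.  F1 is the
positive-class (binary) F1 — the quantity of interest for rare-event
detection — never macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetricRow",
    "LearningCurve",
    "confusion_counts",
    "metrics_from_counts",
    "naive_all_positive_f1",
    "make_metric_row",
    "stratified_metrics",
    "disparity",
    "f1_gain",
    "assemble_learning_curves",
    "rows_to_dataframe",
    "write_results_csv",
    "read_results_csv",
]

RESULTS_COLUMNS = [
    "outcome",
    "variant",
    "budget",
    "subgroup",
    "n_test",
    "tp",
    "fp",
    "fn",
    "tn",
    "precision",
    "recall",
    "f1",
    "fnr",
    "seed",
]

DEFAULT_MIN_GROUP_N = 25


@dataclass(frozen=True)
class MetricRow:
    """Confusion counts + derived metrics for one (outcome, variant, budget,
    subgroup) evaluation cell."""

    outcome: str
    variant: str
    budget: int
    subgroup: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    fnr: float
    n_test: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tp + self.fp + self.fn + self.tn != self.n_test:
            raise ValueError("confusion counts must sum to n_test")
        if self.tp + self.fn > 0 and abs(self.recall + self.fnr - 1.0) > 1e-12:
            raise ValueError("recall + fnr must equal 1 when positives exist")


@dataclass
class LearningCurve:
    """MetricRows sharing (outcome, variant, subgroup), ascending budget."""

    outcome: str
    variant: str
    subgroup: str
    rows: list[MetricRow] = field(default_factory=list)

    @property
    def budgets(self) -> list[int]:
        return [r.budget for r in self.rows]

    def metric(self, name: str) -> list[float]:
        return [getattr(r, name) for r in self.rows]


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> tuple[int, int, int, int]:
    """Standard 2x2 counts (tp, fp, fn, tn) with class 1 as positive."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 labels")
    tp = int(((yt == 1) & (yp == 1)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    return tp, fp, fn, tn


def metrics_from_counts(
    tp: int, fp: int, fn: int, tn: int
) -> tuple[float, float, float, float]:
    """(precision, recall, f1, fnr) with zero-denominator conventions."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    fnr = fn / (fn + tp) if fn + tp > 0 else 0.0
    return precision, recall, f1, fnr


def naive_all_positive_f1(prevalence: float) -> float:
    """F1 of the classifier labeling every case positive: 2p / (1 + p)."""
    if not 0.0 < prevalence <= 1.0:
        raise ValueError("prevalence must be in (0,1]")
    return 2.0 * prevalence / (1.0 + prevalence)


def f1_gain(f1_new: float, f1_reference: float) -> float:
    """Difference in F1 between a training composition and its reference."""
    return f1_new - f1_reference


def make_metric_row(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    *,
    outcome: str,
    variant: str,
    budget: int,
    subgroup: str = "overall",
    seed: int = 0,
) -> MetricRow:
    tp, fp, fn, tn = confusion_counts(y_true, y_pred)
    precision, recall, f1, fnr = metrics_from_counts(tp, fp, fn, tn)
    return MetricRow(
        outcome=outcome,
        variant=variant,
        budget=budget,
        subgroup=subgroup,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        f1=f1,
        fnr=fnr,
        n_test=len(y_true),
        seed=seed,
    )


def stratified_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    group_labels: Sequence[str],
    min_group_n: int = DEFAULT_MIN_GROUP_N,
    *,
    outcome: str = "",
    variant: str = "",
    budget: int = 0,
    seed: int = 0,
    include_overall: bool = True,
) -> list[MetricRow]:
    """Per-group MetricRows (groups with n >= min_group_n) plus an overall row.

    Group rows' confusion counts sum to the overall row's counts when no
    group is suppressed.
    """
    if not (len(y_true) == len(y_pred) == len(group_labels)):
        raise ValueError("y_true, y_pred and group_labels must have equal length")
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    groups = np.asarray(group_labels)
    rows: list[MetricRow] = []
    if include_overall:
        rows.append(
            make_metric_row(
                yt, yp, outcome=outcome, variant=variant, budget=budget, seed=seed
            )
        )
    for g in sorted(set(group_labels)):
        mask = groups == g
        if int(mask.sum()) < min_group_n:
            continue
        rows.append(
            make_metric_row(
                yt[mask],
                yp[mask],
                outcome=outcome,
                variant=variant,
                budget=budget,
                subgroup=str(g),
                seed=seed,
            )
        )
    return rows


def disparity(rows: Sequence[MetricRow]) -> float:
    """max F1 - min F1 across the supplied subgroup rows."""
    if len(rows) < 2:
        raise ValueError("disparity needs at least 2 subgroup rows")
    f1s = [r.f1 for r in rows]
    return max(f1s) - min(f1s)


def assemble_learning_curves(rows: Iterable[MetricRow]) -> list[LearningCurve]:
    """Group rows by (outcome, variant, subgroup) and sort by budget.

    Sparse curves (missing budgets) are allowed; duplicate cells are an
    error.  Permutation-invariant in the input order.
    """
    grouped: dict[tuple[str, str, str], list[MetricRow]] = {}
    for row in rows:
        grouped.setdefault((row.outcome, row.variant, row.subgroup), []).append(row)
    curves = []
    for (outcome, variant, subgroup), group_rows in sorted(grouped.items()):
        budgets = [r.budget for r in group_rows]
        if len(set(budgets)) != len(budgets):
            raise ValueError(
                f"duplicate budget in curve ({outcome}, {variant}, {subgroup})"
            )
        curves.append(
            LearningCurve(
                outcome=outcome,
                variant=variant,
                subgroup=subgroup,
                rows=sorted(group_rows, key=lambda r: r.budget),
            )
        )
    return curves


def rows_to_dataframe(rows: Iterable[MetricRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows], columns=RESULTS_COLUMNS)


def write_results_csv(rows: Iterable[MetricRow], path) -> None:
    """Tidy results CSV — the machine-readable twin of the summary tables."""
    rows_to_dataframe(rows).to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESULTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed results CSV, missing columns: {sorted(missing)}")
    return df
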