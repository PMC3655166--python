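"""Diagnostic performance evaluation and test-vs-test comparison.

Contingency metrics (sensitivity, specificity, PPV, NPV, accuracy),
ROC/AUC via the rank (Mann–Whitney) identity with midranks for ties and
the Hanley–McNeil standard error, an unpaired Z comparison of two AUCs,
and a 2×2 chi-square comparison of two tests' correct-call counts.

Metrics with an empty margin are reported as not available (``None``),
never as zero. Percentages are additionally offered rounded to integer
percent, the convention clinical biomarker studies print, with raw
proportions always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CONTROL, TUMOR


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 diagnostic counts: disease status × test call."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def correct(self) -> int:
        return self.tp + self.tn

    @classmethod
    def from_calls(cls, calls: pd.Series, labels: pd.Series,
                   positive: str = TUMOR) -> "ContingencyTable":
        labels = labels.reindex(calls.index)
        truth = labels == positive
        called = calls == positive
        return cls(
            tp=int((truth & called).sum()),
            fp=int((~truth & called).sum()),
            fn=int((truth & ~called).sum()),
            tn=int((~truth & ~called).sum()),
        )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass
class MetricReport:
    """Proportion metrics of one contingency table."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def as_percent(self) -> dict[str, int | None]:
        """Integer-percent view (round-half-away from the raw proportions)."""
        out = {}
        for name, value in vars(self).items():
            out[name] = None if value is None else int(np.floor(value * 100 + 0.5))
        return out


def contingency_metrics(table: ContingencyTable) -> MetricReport:
    """Sensitivity, specificity, PPV, NPV and accuracy of one test."""
    return MetricReport(
        sensitivity=_ratio(table.tp, table.tp + table.fn),
        specificity=_ratio(table.tn, table.tn + table.fp),
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        accuracy=_ratio(table.correct, table.total),
    )


def threshold_calls(values: pd.Series, labels: pd.Series,
                    cutoff: float) -> ContingencyTable:
    """Dichotomize an analyte at its upper limit of normal.

    A sample is positive iff its value is strictly greater than the
    cutoff — a value at the upper limit of normal is still normal.
    """
    calls = pd.Series(np.where(values > cutoff, TUMOR, CONTROL),
                      index=values.index)
    return ContingencyTable.from_calls(calls, labels)


@dataclass
class RocResult:
    auc: float
    se: float
    n_positive: int
    n_negative: int
    curve: pd.DataFrame  # columns fpr, tpr, ordered by threshold


def roc_auc(scores: pd.Series, labels: pd.Series,
            positive: str = TUMOR) -> RocResult:
    """AUC by the rank identity with midranks; Hanley–McNeil SE.

    AUC = (R₊ − n₊(n₊+1)/2) / (n₊ n₋) with R₊ the midrank sum of
    positive-class scores — identical to the probability a random positive
    outranks a random negative (ties counting one half).
    """
    labels = labels.reindex(scores.index)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = stats.rankdata(scores.to_numpy())
    auc = (ranks[pos.to_numpy()].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))

    order = np.argsort(-scores.to_numpy(), kind="stable")
    y = pos.to_numpy()[order]
    tpr = np.concatenate([[0.0], np.cumsum(y) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(~y) / n_neg])
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return RocResult(float(auc), se, n_pos, n_neg, curve)


def compare_auc(a: RocResult, b: RocResult) -> tuple[float, float]:
    """Unpaired Z test of two AUCs measured on independent cohorts.

    Z = (AUC_a − AUC_b) / √(SE_a² + SE_b²), two-sided normal p.
    """
    pooled = np.hypot(a.se, b.se)
    if pooled == 0:
        raise ValueError("both AUC standard errors are zero")
    z = (a.auc - b.auc) / pooled
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class CallRateComparison:
    chi2: float
    p_value: float
    chi2_yates: float
    p_value_yates: float
    table: np.ndarray  # 2×2: (test A, test B) × (correct, incorrect)


def compare_call_rates(a: ContingencyTable, b: ContingencyTable) -> CallRateComparison:
    """Chi-square comparison of two tests' correct-call counts.

    Builds the 2×2 table (correct, incorrect) × (test A, test B) and
    reports the Pearson chi-square both without and with the Yates
    continuity correction; the uncorrected value is the headline.
    """
    obs = np.array([
        [a.correct, a.total - a.correct],
        [b.correct, b.total - b.correct],
    ], dtype=float)
    expected = stats.contingency.expected_freq(obs)
    if (expected < 1).any():
        warnings.warn("expected cell count below 1; consider an exact test",
                      stacklevel=2)
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    chi2_y, p_y, _, _ = stats.chi2_contingency(obs, correction=True)
    return CallRateComparison(float(chi2), float(p), float(chi2_y), float(p_y), obs)


def proportion_percent(successes: int, total: int) -> int:
    """A count ratio as an integer percent (round half away from zero)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(successes / total * 100 + 0.5))
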