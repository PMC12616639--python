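"""Univariate statistics of the bidding experiment.

Condition-level comparisons: paired t-test on per-subject mean bids,
Shapiro-Wilk normality check, Wilcoxon signed-rank tests on the four
ratings, and Cronbach's alpha for the internal consistency of each rating
scale.  Pairing is by subject: each subject contributes one mean over the
labeled products and one over the unlabeled products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import RATING_COLUMNS, Dataset

__all__ = [
    "PairedSample",
    "RatingMatrix",
    "ConditionSummary",
    "paired_t",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "cronbach_alpha",
    "rating_matrix",
    "alpha_by_characteristic",
    "paired_by_subject",
    "condition_summary",
]

MEASURES = ["bid", *RATING_COLUMNS]


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length vectors paired by subject (labeled vs unlabeled)."""

    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired vectors must be 1-d and of equal length")
        if len(a) < 2:
            raise ValueError("paired sample needs at least 2 pairs")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass(frozen=True)
class RatingMatrix:
    """Cases x items matrix for internal-consistency analysis."""

    values: np.ndarray
    orientation: str = "cases=subjects"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("rating matrix needs >= 2 cases and >= 2 items")
        if np.isnan(v).any():
            raise ValueError("rating matrix must not contain missing entries")
        object.__setattr__(self, "values", v)


def paired_t(sample: PairedSample) -> tuple[float, int, float]:
    """Classical paired t-test on the differences; two-sided."""
    d = sample.differences
    if np.std(d, ddof=1) == 0:
        raise ValueError("paired t-test undefined: differences have zero variance")
    res = stats.ttest_rel(sample.values_a, sample.values_b)
    return float(res.statistic), int(len(d) - 1), float(res.pvalue)


def shapiro_wilk(values) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(sample: PairedSample) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on the paired differences.

    Zero differences are excluded (classical treatment).  The exact null
    distribution is used for n <= 25 without ties in |d|; otherwise the
    normal approximation with tie correction.  The statistic returned is
    the sum of ranks of the positive differences.
    """
    d = sample.differences
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; Wilcoxon test undefined")
    ties = len(np.unique(np.abs(d))) < len(d)
    mode = "exact" if (len(d) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=mode, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def cronbach_alpha(matrix: RatingMatrix) -> float:
    """alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)).

    Variances use the unbiased (n-1) denominator.  With pathological
    (anti-correlated) items alpha can be negative; a zero total-score
    variance is an error.
    """
    v = matrix.values
    k = v.shape[1]
    item_var = v.var(axis=0, ddof=1)
    total_var = v.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def rating_matrix(dataset: Dataset, characteristic: str, condition: int) -> RatingMatrix:
    """Subjects-as-cases matrix for one rating scale within one label condition.

    Items are the products of that condition (30 in the default design).
    """
    if characteristic not in RATING_COLUMNS:
        raise ValueError(f"unknown rating characteristic {characteristic!r}")
    sub = dataset.records[dataset.records["label"] == condition]
    wide = sub.pivot(index="subject_id", columns="product_id", values=characteristic)
    if wide.isna().any().any():
        wide = wide.dropna(axis=1)
    return RatingMatrix(values=wide.to_numpy(dtype=float))


def alpha_by_characteristic(dataset: Dataset) -> dict[str, float]:
    """Cronbach's alpha per rating scale, averaged over the two conditions."""
    out = {}
    for char in RATING_COLUMNS:
        alphas = [
            cronbach_alpha(rating_matrix(dataset, char, cond)) for cond in (0, 1)
        ]
        out[char] = float(np.mean(alphas))
    return out


def paired_by_subject(dataset: Dataset, measure: str) -> PairedSample:
    """Per-subject means of ``measure`` over labeled (a) vs unlabeled (b)."""
    means = (
        dataset.records.groupby(["subject_id", "label"], sort=True)[measure]
        .mean()
        .unstack("label")
    )
    if means.isna().any().any():
        means = means.dropna()
    return PairedSample(
        values_a=means[1].to_numpy(), values_b=means[0].to_numpy()
    )


@dataclass
class ConditionSummary:
    """Per-condition means/SDs plus the paired condition comparisons."""

    table: pd.DataFrame  # index (condition, measure); columns mean, sd
    tests: dict[str, dict[str, float]]


def condition_summary(dataset: Dataset) -> ConditionSummary:
    """Summaries per label condition and the study's paired tests.

    The bid comparison is a paired t-test (with a Shapiro-Wilk check of the
    per-subject difference distribution); the four ratings are compared
    with Wilcoxon signed-rank tests.
    """
    rec = dataset.records
    table = (
        rec.groupby("label")[MEASURES]
        .agg(["mean", "std"])
        .stack(level=0, future_stack=True)
        .rename(columns={"std": "sd"})
    )
    table.index.names = ["condition", "measure"]

    tests: dict[str, dict[str, float]] = {}
    bid_pairs = paired_by_subject(dataset, "bid")
    t, df, p = paired_t(bid_pairs)
    w_stat, w_p = shapiro_wilk(bid_pairs.differences)
    tests["bid"] = {
        "test": "paired_t",
        "statistic": t,
        "df": df,
        "p_value": p,
        "shapiro_W": w_stat,
        "shapiro_p": w_p,
    }
    for char in RATING_COLUMNS:
        stat, p = wilcoxon_signed_rank(paired_by_subject(dataset, char))
        tests[char] = {"test": "wilcoxon", "statistic": stat, "p_value": p}
    return ConditionSummary(table=table, tests=tests)
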