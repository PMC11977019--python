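"""Nonparametric comparison of detection models across paired subjects.

Detection metrics (precision, recall, F1) violate the assumptions of
parametric models, so model comparison is rank-based throughout: a Friedman
test across k >= 3 models evaluated on the same subjects, Wilcoxon
signed-rank tests for pairs, and Benjamini–Hochberg correction of each
family of pairwise p-values to control the false discovery rate.

The Friedman statistic is the classic one,

    chi2_F = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1),

with within-subject average ranks on ties and a chi-square reference
distribution on k-1 degrees of freedom; all-tied data gives chi2 = 0, p = 1.

The Wilcoxon statistic is T+ (sum of ranks of positive differences, zero
differences dropped, ties mid-ranked).  The two-sided p-value is exact —
computed over the full 2^n sign-pattern distribution — for n <= 25, and a
normal approximation with tie and continuity corrections beyond.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import ValidationError

__all__ = [
    "PairedMetricMatrix",
    "TestResult",
    "friedman_test",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
    "compare_models",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class PairedMetricMatrix:
    """n_subjects x k_models matrix of one metric, fully observed.

    Subjects with any undefined (missing) metric are dropped listwise with a
    warning before construction via :meth:`from_frame`."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    model_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValidationError("values must be 2-D (subjects x models)")
        if v.shape != (len(self.subject_ids), len(self.model_ids)):
            raise ValidationError("values shape does not match id lists")
        if np.isnan(v).any():
            raise ValidationError("missing cells; drop subjects listwise first")

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "PairedMetricMatrix":
        """Build from a subjects x models DataFrame, dropping incomplete rows."""
        complete = frame.dropna(axis=0)
        dropped = sorted(set(frame.index) - set(complete.index))
        if dropped:
            warnings.warn(
                f"dropping subjects with undefined metrics: {dropped}",
                stacklevel=2,
            )
        return PairedMetricMatrix(
            values=complete.to_numpy(float),
            subject_ids=tuple(map(str, complete.index)),
            model_ids=tuple(map(str, complete.columns)),
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float  # chi2 for Friedman, T+ for Wilcoxon
    p_value: float
    n: int
    dof: int | None = None  # Friedman only
    p_adjusted: float | None = None
    method: str = ""


def friedman_test(matrix: PairedMetricMatrix) -> TestResult:
    """Friedman rank test across k >= 3 models on n >= 2 paired subjects."""
    values = np.asarray(matrix.values, float)
    n, k = values.shape
    if k < 3:
        raise ValidationError(
            f"Friedman test needs k >= 3 models, got {k}; use the Wilcoxon "
            "signed-rank test for a pair"
        )
    if n < 2:
        raise ValidationError(f"Friedman test needs n >= 2 subjects, got {n}")
    ranks = np.apply_along_axis(sps.rankdata, 1, values)  # average ranks on ties
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)  # guard round-off on fully tied data
    dof = k - 1
    p = float(sps.chi2.sf(chi2, dof))
    return TestResult(statistic=chi2, p_value=p, n=n, dof=dof, method="friedman")


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Exact counts of 2*T+ over all 2^n sign patterns, by dynamic
    programming; ``double_ranks`` are the (integer) doubled mid-ranks."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of paired samples ``a`` vs ``b``.

    T+ sums the ranks of positive differences of (a - b); zero differences
    are dropped, ties mid-ranked.  Exact two-sided p (full sign-pattern
    distribution, symmetric about M/2 where M is the rank total) for
    n <= 25 after zero removal; normal approximation with tie and continuity
    corrections otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("a and b must be equal-length 1-D vectors")
    diff = a - b
    diff = diff[diff != 0.0]
    n = diff.size
    if n == 0:
        warnings.warn("all differences zero; degenerate Wilcoxon result")
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="wilcoxon-degenerate")
    ranks = sps.rankdata(np.abs(diff))
    t_plus = float(ranks[diff > 0].sum())
    total = float(ranks.sum())  # n(n+1)/2

    if n <= EXACT_WILCOXON_MAX_N:
        double_ranks = np.rint(2.0 * ranks).astype(int)
        counts = _signed_rank_distribution(double_ranks)
        # distribution of 2*T+ is symmetric about total; two-sided p is the
        # probability of an outcome at least as far from the centre
        dev = abs(2.0 * t_plus - total)
        support = np.arange(counts.size, dtype=float)
        tail = counts[np.abs(support - total) >= dev - 1e-9].sum()
        p = float(min(1.0, tail / counts.sum()))
        method = "wilcoxon-exact"
    else:
        mean = total / 2.0
        # variance with tie correction: sum(r_i^2)/4
        var = float(np.sum(ranks**2)) / 4.0
        dev = abs(t_plus - mean)
        z = max(dev - 0.5, 0.0) / np.sqrt(var)  # continuity corrected
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "wilcoxon-normal"
    return TestResult(statistic=t_plus, p_value=p, n=n, method=method)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; monotone in
    the sorted order and never below the raw p-value."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def compare_models(
    matrix: PairedMetricMatrix, metric_name: str = "f1"
) -> pd.DataFrame:
    """Full model-comparison report for one metric.

    With k >= 3 models: a Friedman row followed by all pairwise Wilcoxon
    rows; with k = 2: Wilcoxon only.  Benjamini–Hochberg correction is
    applied within the family of pairwise comparisons of this one metric.
    T+ ranks positive values of (first-listed model − second-listed model),
    so T+ = 0 means the second model never fell below the first.
    """
    k = len(matrix.model_ids)
    if k < 2:
        raise ValidationError("need at least 2 models to compare")
    rows: list[dict] = []
    if k >= 3:
        fr = friedman_test(matrix)
        rows.append(
            {
                "comparison": " vs ".join(matrix.model_ids),
                "test": "friedman",
                "metric": metric_name,
                "n": fr.n,
                "dof": fr.dof,
                "statistic": fr.statistic,
                "p_value": fr.p_value,
                "p_adjusted": np.nan,
            }
        )
    pair_results = []
    for i, j in itertools.combinations(range(k), 2):
        res = wilcoxon_signed_rank(matrix.values[:, i], matrix.values[:, j])
        pair_results.append(((i, j), res))
    adjusted = benjamini_hochberg([r.p_value for _, r in pair_results])
    for ((i, j), res), p_adj in zip(pair_results, adjusted):
        rows.append(
            {
                "comparison": f"{matrix.model_ids[i]} vs {matrix.model_ids[j]}",
                "test": res.method,
                "metric": metric_name,
                "n": res.n,
                "dof": 1,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "p_adjusted": p_adj,
            }
        )
    return pd.DataFrame(rows)
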