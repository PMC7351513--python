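"""Pre/post paired comparisons, univariate regressions and Pearson matrix.

Paired differences are gated on a Shapiro-Wilk normality check at 0.05:
normal-looking differences go to the paired t-test, the rest to a sign-flip
permutation test on the mean difference with 10,000 Monte-Carlo rounds
(exact enumeration of all 2^n sign patterns whenever that is no more work).
All p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ROUNDS = 10_000
NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class PairedSample:
    """Aligned pre/post measurements for a set of subjects."""

    subject_ids: tuple[str, ...]
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)
        if not (len(self.subject_ids) == pre.size == post.size):
            raise ValueError("subject_ids, pre and post must be aligned")
        if pre.size < 2:
            raise ValueError("need at least 2 paired observations")
        if np.isnan(pre).any() or np.isnan(post).any():
            raise ValueError("missing values are not allowed in a paired sample")

    @property
    def differences(self) -> np.ndarray:
        return self.post - self.pre

    @property
    def n(self) -> int:
        return int(self.pre.size)


@dataclass(frozen=True)
class ComparisonResult:
    method: str  # "t_paired" or "permutation"
    statistic: float
    p_value: float
    n: int
    mean_pre: float
    mean_post: float
    se_pre: float
    se_post: float


@dataclass(frozen=True)
class RegressionResult:
    estimate: float  # OLS slope, response units per predictor unit
    p_value: float
    n: int
    intercept: float = math.nan
    stderr: float = math.nan


def permutation_test_paired(
    differences: Sequence[float],
    rounds: int = DEFAULT_ROUNDS,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """Two-sided sign-flip permutation p-value for mean(differences) = 0.

    The statistic is the mean difference. When ``2**n <= rounds`` all sign
    assignments are enumerated and the p-value is exact; otherwise ``rounds``
    random sign vectors are drawn from a generator seeded with ``seed`` and
    the observed assignment is counted once (add-one convention), so the
    Monte-Carlo p-value is never zero. ``method`` ("exact"/"monte-carlo")
    overrides the automatic branch choice.
    """
    if method not in ("auto", "exact", "monte-carlo"):
        raise ValueError("method must be 'auto', 'exact' or 'monte-carlo'")
    d = np.asarray(differences, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one difference")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    observed = abs(float(np.mean(d)))
    if np.all(d == 0):
        return 1.0
    n = d.size
    exact = (n <= 62 and 2**n <= rounds) if method == "auto" else method == "exact"
    if exact:
        if n > 25:
            raise ValueError("exact enumeration is infeasible beyond n = 25")
        # exact: enumerate every sign pattern; identity pattern included
        hits = 0
        for signs in itertools.product((1.0, -1.0), repeat=n):
            if abs(float(np.dot(signs, d))) / n >= observed - 1e-12:
                hits += 1
        return hits / 2**n
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(rounds, n))
    perm_means = np.abs(signs @ d) / n
    hits = int(np.sum(perm_means >= observed - 1e-12))
    return (1 + hits) / (rounds + 1)


def paired_comparison(
    sample: PairedSample,
    alpha: float = 0.05,
    rounds: int = DEFAULT_ROUNDS,
    seed: int | None = None,
    force_method: str | None = None,
) -> ComparisonResult:
    """Pre/post comparison: paired t-test or sign-flip permutation test.

    The branch is chosen by a Shapiro-Wilk test on the differences (normal at
    the 0.05 level -> t-test); ``force_method`` ("t_paired"/"permutation")
    overrides the gate, mainly for testing.
    """
    d = sample.differences
    n = sample.n
    summary = dict(
        n=n,
        mean_pre=float(np.mean(sample.pre)),
        mean_post=float(np.mean(sample.post)),
        se_pre=float(stats.sem(sample.pre)),
        se_post=float(stats.sem(sample.post)),
    )
    if np.all(d == d[0]) and d[0] == 0:
        return ComparisonResult(method="t_paired", statistic=0.0, p_value=1.0, **summary)

    if force_method is None:
        if np.ptp(d) == 0:  # Shapiro undefined for constant input
            method = "permutation"
        else:
            method = "t_paired" if stats.shapiro(d).pvalue > NORMALITY_ALPHA else "permutation"
    else:
        method = force_method

    if method == "t_paired":
        t_res = stats.ttest_rel(sample.post, sample.pre)
        return ComparisonResult(
            method="t_paired",
            statistic=float(t_res.statistic),
            p_value=float(t_res.pvalue),
            **summary,
        )
    if method == "permutation":
        p = permutation_test_paired(d, rounds=rounds, seed=seed)
        return ComparisonResult(
            method="permutation", statistic=float(np.mean(d)), p_value=p, **summary
        )
    raise ValueError(f"unknown method {method!r}")


def univariate_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """OLS slope of y on x with the two-sided t-test p-value for slope = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")
    res = stats.linregress(x, y)
    return RegressionResult(
        estimate=float(res.slope),
        p_value=float(res.pvalue),
        n=int(x.size),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
    )


def pearson_matrix(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pairwise-complete Pearson correlation matrix with p-values and n.

    Returns ``{"r": ..., "p": ..., "n": ...}`` DataFrames indexed by column.
    A zero-variance column's correlations are NaN. p-values come from
    ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns")
    k = len(cols)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            xi = table[cols[i]].to_numpy(dtype=float)
            xj = table[cols[j]].to_numpy(dtype=float)
            mask = ~(np.isnan(xi) | np.isnan(xj))
            n = int(mask.sum())
            n_mat[i, j] = n_mat[j, i] = n
            if n < 3:
                continue
            xi, xj = xi[mask], xj[mask]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue  # zero variance: flagged missing
            if i == j:
                r_mat[i, j] = 1.0
                p_mat[i, j] = 0.0
                continue
            r, p = stats.pearsonr(xi, xj)
            r_mat[i, j] = r_mat[j, i] = float(r)
            p_mat[i, j] = p_mat[j, i] = float(p)
    idx = pd.Index(cols)
    return {
        "r": pd.DataFrame(r_mat, index=idx, columns=idx),
        "p": pd.DataFrame(p_mat, index=idx, columns=idx),
        "n": pd.DataFrame(n_mat, index=idx, columns=idx),
    }
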