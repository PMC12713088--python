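"""Exact and rank statistics shared across the pipeline.

Gene-set overlaps are scored with the hypergeometric distribution and the
representation factor RF = observed/expected overlap. Two-tailed
hypergeometric p-values are convention-dependent: the default here is the
minimum-likelihood rule (sum the probabilities of all outcomes no more
likely than the observed one); doubling the smaller one-sided tail is
available as an alternative. All tail sums are accumulated from log-pmf
values so extreme tails do not underflow.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

TailConvention = Literal["min_likelihood", "double_one_tail"]

#: relative log-space slack when comparing pmf values for the
#: minimum-likelihood rule; guards against floating round-off at ties
_MINLIKE_EPS = 1e-7


@dataclass(frozen=True)
class OverlapResult:
    """Enrichment of the overlap between two gene sets in a fixed universe.

    N is the universe size, K and n the two set sizes, k the observed
    overlap. ``expected`` is the overlap size under independence, K*n/N, and
    ``rf`` the representation factor k/expected.
    """

    N: int
    K: int
    n: int
    k: int
    expected: float
    rf: float
    p_one: float
    p_two: float
    tail_convention: TailConvention

    def __post_init__(self) -> None:
        lo, hi = max(0, self.K + self.n - self.N), min(self.K, self.n)
        if not lo <= self.k <= hi:
            raise ValueError(
                f"overlap k={self.k} outside hypergeometric support [{lo}, {hi}]"
            )


def _check_hypergeom_args(k: int, K: int, n: int, N: int) -> None:
    if N < 1:
        raise ValueError("universe size N must be >= 1")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"set sizes K={K}, n={n} must lie in [0, N={N}]")
    lo, hi = max(0, K + n - N), min(K, n)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside hypergeometric support [{lo}, {hi}]")


def hypergeom_tail(
    k: int,
    K: int,
    n: int,
    N: int,
    tail: Literal["upper", "lower", "two"] = "upper",
    tail_convention: TailConvention = "min_likelihood",
) -> float:
    """Tail probability of X ~ Hypergeometric(N, K, n) at the observed k.

    ``upper`` is P(X >= k) (enrichment), ``lower`` is P(X <= k)
    (depletion). ``two`` follows ``tail_convention``: either the
    minimum-likelihood sum or twice the smaller one-sided tail, capped at 1.
    """
    _check_hypergeom_args(k, K, n, N)
    if tail == "upper":
        return float(np.exp(sps.hypergeom.logsf(k - 1, N, K, n)))
    if tail == "lower":
        return float(np.exp(sps.hypergeom.logcdf(k, N, K, n)))
    if tail != "two":
        raise ValueError(f"unknown tail {tail!r}")
    if tail_convention == "double_one_tail":
        lower = hypergeom_tail(k, K, n, N, "lower")
        upper = hypergeom_tail(k, K, n, N, "upper")
        return float(min(1.0, 2.0 * min(lower, upper)))
    if tail_convention != "min_likelihood":
        raise ValueError(f"unknown tail convention {tail_convention!r}")
    support = np.arange(max(0, K + n - N), min(K, n) + 1)
    logpmf = sps.hypergeom.logpmf(support, N, K, n)
    log_at_k = sps.hypergeom.logpmf(k, N, K, n)
    keep = logpmf <= log_at_k + _MINLIKE_EPS
    # log-sum-exp over the kept outcomes
    m = logpmf[keep].max()
    return float(min(1.0, np.exp(m) * np.exp(logpmf[keep] - m).sum()))


def representation_factor(k: int, K: int, n: int, N: int) -> float:
    """Observed/expected overlap ratio k*N/(K*n)."""
    if min(K, n, N) <= 0:
        raise ValueError("K, n and N must be positive")
    return k * N / (K * n)


def overlap_result(
    k: int,
    K: int,
    n: int,
    N: int,
    tail_convention: TailConvention = "min_likelihood",
) -> OverlapResult:
    """Bundle one- and two-tailed hypergeometric p with RF for an overlap."""
    _check_hypergeom_args(k, K, n, N)
    return OverlapResult(
        N=N,
        K=K,
        n=n,
        k=k,
        expected=K * n / N,
        rf=representation_factor(k, K, n, N),
        p_one=hypergeom_tail(k, K, n, N, "upper"),
        p_two=hypergeom_tail(k, K, n, N, "two", tail_convention),
        tail_convention=tail_convention,
    )


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_corr_matrix(
    values,
    transform: Literal["identity", "log2p1"] = "log2p1",
):
    """Sample-by-sample Pearson correlation of a gene x sample matrix.

    Accepts a pandas DataFrame (genes as rows, samples as columns) or a 2-D
    array. Binding/mark signals are heavy-tailed, so the default correlates
    log2(value + 1); pass ``transform='identity'`` for raw values.
    """
    import pandas as pd

    df = values if isinstance(values, pd.DataFrame) else pd.DataFrame(np.asarray(values))
    if df.shape[0] < 3:
        raise ValueError("need at least 3 genes to correlate samples")
    x = df.to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [str(df.columns[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance sample(s): {', '.join(bad)}")
    corr = np.corrcoef(x, rowvar=False)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


# ---------------------------------------------------------------------------
# rank tests

_EXACT_LIMIT = 12  # combined sample size up to which the U null is enumerated


def _mwu_exact(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    # Enumerate every assignment of the pooled observations to group labels;
    # midranks make the statistic well defined under ties.
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    idx = range(len(pooled))
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = np.array(
        [sum(ranks[i] for i in combo) - na * (na + 1) / 2
         for combo in itertools.combinations(idx, na)]
    )
    eps = 1e-9
    p_greater = np.mean(us >= u_obs - eps)
    p_less = np.mean(us <= u_obs + eps)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return float(u_obs), float(p)


def rank_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: Literal["unpaired_mwu", "paired_signed_rank"] = "unpaired_mwu",
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired) test.

    The unpaired null distribution is enumerated exactly for combined sizes
    up to 12 (ties included, via midranks); larger samples use the normal
    approximation with tie and continuity corrections. A request for a
    "paired Mann-Whitney" is served by the signed-rank test, which is the
    rank test actually defined for paired data.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if mode == "paired_signed_rank":
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        if len(a) == 0:
            raise ValueError("empty groups")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        res = sps.wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
        return float(res.statistic), float(res.pvalue)
    if mode != "unpaired_mwu":
        raise ValueError(f"unknown mode {mode!r}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if len(a) + len(b) <= _EXACT_LIMIT:
        return _mwu_exact(a, b, alternative)
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)
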