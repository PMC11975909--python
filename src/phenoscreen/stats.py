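"""Nonparametric statistics: Mann-Whitney U and Spearman rank correlation.

Self-contained implementations used throughout the package. The Mann-Whitney
test is exact (full enumeration over group assignments of the pooled ranks)
for small samples and a tie-corrected, continuity-corrected normal
approximation otherwise. Spearman's rho uses average ranks for ties, with an
exact permutation p-value for small n and a t-approximation for larger n.
All p-values are two-sided by default, matching how this class of per-well
and per-donor comparisons is conventionally reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm as _norm, rankdata, t as _t

#: exact Mann-Whitney enumeration when n_a + n_b <= this
EXACT_MW_THRESHOLD = 12
#: exact Spearman permutation enumeration when n <= this
EXACT_SPEARMAN_THRESHOLD = 10


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    pvalue: float
    method: str                 # "exact" | "normal-approx" | "t-approx"
    n: tuple[int, ...]
    tie_count: int = 0
    undefined: bool = False     # e.g. Spearman on a constant vector


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b, alternative: str = "two-sided",
                 method: str = "auto",
                 exact_threshold: int = EXACT_MW_THRESHOLD) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    The statistic is U of the first sample (rank sum of ``a`` minus its
    minimum). Exact p-values enumerate all C(n_a + n_b, n_a) assignments of
    the pooled (average) ranks when the total sample is small; otherwise a
    normal approximation with tie correction and continuity correction is
    used. ``alternative`` is "two-sided", "greater" (a tends larger) or
    "less".
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    _, tie_sizes = np.unique(pooled, return_counts=True)
    tie_count = int((tie_sizes - 1).sum())
    u_obs = _u_statistic(ranks[:n_a], n_a)

    use_exact = (method == "exact") or (
        method == "auto" and n_a + n_b <= exact_threshold)

    if use_exact:
        n_le = n_ge = total = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(combo)], n_a)
            total += 1
            if u <= u_obs + 1e-9:
                n_le += 1
            if u >= u_obs - 1e-9:
                n_ge += 1
        p_le, p_ge = n_le / total, n_ge / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return TestResult(statistic=u_obs, pvalue=p, method="exact",
                          n=(n_a, n_b), tie_count=tie_count)

    # tie-corrected normal approximation with continuity correction
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    tie_term = float(((tie_sizes ** 3 - tie_sizes)).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:       # all pooled values identical
        return TestResult(statistic=u_obs, pvalue=1.0, method="normal-approx",
                          n=(n_a, n_b), tie_count=tie_count)
    sd = math.sqrt(var)

    def _z(shift):
        return (u_obs - mu + shift) / sd

    if alternative == "two-sided":
        # continuity correction pulls |U - mu| toward zero by 1/2
        z = max(0.0, abs(u_obs - mu) - 0.5) / sd
        p = min(1.0, 2.0 * float(_norm.sf(z)))
    elif alternative == "greater":
        p = float(_norm.sf(_z(-0.5)))
    elif alternative == "less":
        p = float(_norm.cdf(_z(0.5)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(statistic=u_obs, pvalue=p, method="normal-approx",
                      n=(n_a, n_b), tie_count=tie_count)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        return math.nan
    return float(rx @ ry) / denom


def spearman(x, y, exact_threshold: int = EXACT_SPEARMAN_THRESHOLD) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks. For n <= the exact
    threshold the p-value enumerates all n! permutations of one rank vector
    (p = fraction of permutations with |rho| at least as extreme); above it
    a t-approximation with n-2 degrees of freedom is used. Constant input
    vectors yield an undefined-flagged result rather than an exception.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(statistic=math.nan, pvalue=math.nan,
                          method="undefined", n=(n,), undefined=True)
    rx = rankdata(x)
    ry = rankdata(y)
    tie_count = int((len(rx) - len(np.unique(x))) + (len(ry) - len(np.unique(y))))
    rho = _rho_of_ranks(rx, ry)

    if n <= exact_threshold:
        # exact permutation null: permute one rank vector, chunked/vectorized
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        count = 0
        total = 0
        chunk: list[tuple] = []
        chunk_size = 40320
        threshold_val = abs(rho) - 1e-12

        def _flush(chunk):
            nonlocal count, total
            if not chunk:
                return
            perm = np.asarray(chunk, dtype=np.float64)
            rhos = (perm - ry.mean()) @ rx_c / denom
            count += int((np.abs(rhos) >= threshold_val).sum())
            total += len(chunk)

        for p in itertools.permutations(ry):
            chunk.append(p)
            if len(chunk) >= chunk_size:
                _flush(chunk)
                chunk = []
        _flush(chunk)
        return TestResult(statistic=rho, pvalue=count / total, method="exact",
                          n=(n,), tie_count=tie_count)

    # t-approximation
    if 1.0 - rho * rho < 1e-15:
        p = 0.0
    else:
        t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(_t.sf(abs(t_stat), df=n - 2))
    return TestResult(statistic=rho, pvalue=min(1.0, p), method="t-approx",
                      n=(n,), tie_count=tie_count)
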