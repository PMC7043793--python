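"""Inferential primitives used by the analysis modules.

Self-contained implementations of the Mann-Whitney U test (exact enumeration
for small samples, tie/continuity-corrected normal approximation otherwise),
the Benjamini-Hochberg step-up FDR adjustment, and the delta-delta-Ct relative
expression formula for qPCR.

The Mann-Whitney statistic reported is U of the first sample,
``U_x = R_x - n(n+1)/2`` with midranks.  ``alternative="less"`` tests the
hypothesis that ``x`` is stochastically smaller than ``y`` (small U), which is
the convention used by the connectivity report where smaller shortest-path
distances mean higher connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "CtQuadruple",
    "mann_whitney_u",
    "bh_adjust",
    "delta_delta_ct",
]

EXACT_MAX_N = 10  # largest per-sample size for the exact enumeration branch


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact_enumeration" | "normal_approx"
    alternative: str  # "two_sided" | "less" | "greater"


@dataclass(frozen=True)
class CtQuadruple:
    """qPCR cycle thresholds for target/reference genes in test/control samples."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        vals = (
            self.ct_target_test,
            self.ct_reference_test,
            self.ct_target_control,
            self.ct_reference_control,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("Ct values must be finite")
        if not all(v > 0 for v in vals):
            raise ValueError("Ct values are cycle counts and must be positive")


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank assignments giving each U value, for tie-free samples.

    ``counts[u]`` is the number of the C(n+m, n) equally likely ways of
    choosing which pooled ranks belong to x that yield statistic U = u,
    for u in 0..n*m.  Classic recurrence c(n,m,u) = c(n-1,m,u-m) + c(n,m-1,u).
    """
    if n == 0 or m == 0:
        return (1,)
    a = np.asarray(_u_counts(n - 1, m), dtype=object)
    b = np.asarray(_u_counts(n, m - 1), dtype=object)
    out = np.zeros(n * m + 1, dtype=object)
    out[m : m + a.size] += a
    out[: b.size] += b
    return tuple(int(v) for v in out)


def _exact_single(x: np.ndarray, y: np.ndarray, u_obs: float, alternative: str) -> TestResult:
    """Exact Mann-Whitney p when one sample has a single observation.

    Under the permutation null every pooled value is equally likely to be the
    singleton, so the U distribution is enumerated directly in O(N log N);
    midranks make this correct under ties as well.
    """
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    srt = np.sort(pooled)
    less = np.searchsorted(srt, pooled, side="left")
    eq = np.searchsorted(srt, pooled, side="right") - less
    if n == 1:
        u_all = less + 0.5 * (eq - 1)  # U of each candidate singleton x
    else:  # m == 1: U_x = n*m - U_y
        u_all = n - (less + 0.5 * (eq - 1))
    total = pooled.size
    p_less = float((u_all <= u_obs + 1e-9).sum()) / total
    p_greater = float((u_all >= u_obs - 1e-9).sum()) / total
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return TestResult(float(u_obs), p, "exact_enumeration", alternative)


def mann_whitney_u(x, y, alternative: str = "two_sided") -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact p-values by full enumeration of rank assignments when both samples
    have at most ``EXACT_MAX_N`` observations and there are no ties; otherwise
    a normal approximation with tie and continuity corrections.
    """
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if min(n, m) == 1 and max(n, m) > EXACT_MAX_N:
        # exact conditional test by enumerating the single observation's
        # insertion position; the normal approximation is useless at n=1
        # (its smallest attainable p is ~0.04 regardless of m)
        return _exact_single(x, y, u, alternative)

    if max(n, m) <= EXACT_MAX_N and not has_ties:
        counts = _u_counts(n, m)
        total = comb(n + m, n)
        ui = int(round(u))
        p_less = sum(counts[: ui + 1]) / total
        p_greater = sum(counts[ui:]) / total
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return TestResult(u, float(p), "exact_enumeration", alternative)

    mu = n * m / 2.0
    nm = n + m
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (nm * (nm - 1))
    sigma2 = n * m / 12.0 * ((nm + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return TestResult(u, 1.0, "normal_approx", alternative)
    sigma = np.sqrt(sigma2)
    if alternative == "less":
        p = norm.cdf((u - mu + 0.5) / sigma)
    elif alternative == "greater":
        p = norm.sf((u - mu - 0.5) / sigma)
    else:
        z = (abs(u - mu) - 0.5) / sigma
        p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
    return TestResult(u, float(p), "normal_approx", alternative)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D list of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def delta_delta_ct(ct: CtQuadruple) -> float:
    """Relative expression 2^(-ddCt) of a target gene, test vs control.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,control - Ct_ref,control).
    """
    ddct = (ct.ct_target_test - ct.ct_reference_test) - (
        ct.ct_target_control - ct.ct_reference_control
    )
    return float(2.0 ** (-ddct))
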