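"""Self-contained statistical primitives.

Each routine here is intentionally small and independently verifiable
against brute-force oracles (exhaustive rank enumeration, closed-form
normal equations, high-precision quantile tables).  The rest of the
package builds on these instead of reaching into assorted library APIs
so that the exact conventions (U orientation, tie handling, continuity
correction) are pinned down in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import special

__all__ = [
    "RankTestResult",
    "RegressionFit",
    "mann_whitney_u",
    "benjamini_hochberg",
    "linear_fit",
    "inverse_normal_cdf",
]

Alternative = Literal["two-sided", "greater", "less"]


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a two-sample rank test.

    ``statistic`` is the Mann-Whitney U of the *first* sample under the
    larger-is-bigger convention: complete separation with every ``x``
    above every ``y`` gives ``U = n1 * n2``.
    """

    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx" | "degenerate"
    n1: int
    n2: int
    tie_corrected: bool


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[float, ...]:
    """Number of rank arrangements giving each U value for sizes (m, n).

    Recurrence N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1); the
    total is C(m + n, m).
    """
    if m == 0 or n == 0:
        return (1.0,)
    a = np.asarray(_u_counts(m - 1, n))
    b = np.asarray(_u_counts(m, n - 1))
    out = np.zeros(m * n + 1)
    out[n : n + a.size] += a
    out[: b.size] += b
    return tuple(out)


def _exact_p(u: int, n1: int, n2: int, alternative: Alternative) -> float:
    counts = np.asarray(_u_counts(n1, n2))
    total = counts.sum()
    cdf = np.cumsum(counts)
    p_le = cdf[u] / total
    p_ge = (total - (cdf[u - 1] if u > 0 else 0.0)) / total
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_le, p_ge))
    if alternative == "greater":
        return p_ge
    return p_le


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two-sided",
    *,
    exact_limit: int = 20,
    continuity: bool = True,
) -> RankTestResult:
    """Two-sample Mann-Whitney U test.

    Uses the exact null distribution (counting recurrence) for tie-free
    samples with ``n1 + n2 <= exact_limit``; otherwise a tie-corrected
    normal approximation, with a continuity correction unless
    ``continuity=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n1 + n2 <= exact_limit:
        p = _exact_p(int(round(u1)), n1, n2, alternative)
        return RankTestResult(u1, p, "exact", n1, n2, False)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(u1, 1.0, "degenerate", n1, n2, True)
    sd = math.sqrt(var)
    d = u1 - mu
    if continuity:
        d = math.copysign(max(abs(d) - 0.5, 0.0), d) if d != 0 else 0.0
    z = d / sd
    if alternative == "two-sided":
        p = 2.0 * _norm_sf(abs(z))
    elif alternative == "greater":
        p = _norm_sf(z)
    else:
        p = _norm_sf(-z)
    return RankTestResult(u1, min(1.0, p), "normal_approx", n1, n2, has_ties)


def _rankdata(a: np.ndarray) -> np.ndarray:
    """Midranks of a 1-d array (average rank for ties), ranks start at 1."""
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(a.size, dtype=float)
    sorted_a = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment; returned in the input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of y on x with r² = 1 - SSR/SST."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("x values are degenerate (all equal)")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ssr = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0 else max(0.0, 1.0 - ssr / sst)
    rsd = math.sqrt(ssr / (x.size - 2)) if x.size > 2 else 0.0
    return RegressionFit(slope, intercept, r2, rsd, int(x.size))


# Acklam's rational approximation to the standard normal quantile,
# refined with one Halley step through erfc; absolute error < 1e-12.
_A = (-3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02,
      1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00)
_B = (-5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02,
      6.680131188771972e01, -1.328068155288572e01)
_C = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00,
      -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00)
_D = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00,
      3.754408661907416e00)
_P_LOW = 0.02425


def _acklam(p: float) -> float:
    if p < _P_LOW:
        q = math.sqrt(-2.0 * math.log(p))
        return ((((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5])
                / ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1.0))
    if p > 1.0 - _P_LOW:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        return -((((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5])
                 / ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1.0))
    q = p - 0.5
    r = q * q
    return ((((((_A[0] * r + _A[1]) * r + _A[2]) * r + _A[3]) * r + _A[4]) * r + _A[5]) * q
            / (((((_B[0] * r + _B[1]) * r + _B[2]) * r + _B[3]) * r + _B[4]) * r + 1.0))


def inverse_normal_cdf(p):
    """Standard normal quantile, accurate to well below 1e-9.

    Accepts a scalar or array-like; every element must lie strictly in
    (0, 1).
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise ValueError("p must lie strictly inside (0, 1)")
    flat = np.atleast_1d(arr).ravel()
    out = np.empty_like(flat)
    for i, pi in enumerate(flat):
        x = _acklam(pi)
        # one Halley refinement via the complementary error function
        e = 0.5 * special.erfc(-x / math.sqrt(2.0)) - pi
        u = e * math.sqrt(2.0 * math.pi) * math.exp(x * x / 2.0)
        out[i] = x - u / (1.0 + x * u / 2.0)
    if arr.ndim == 0:
        return float(out[0])
    return out.reshape(arr.shape)


def _norm_sf(z: float) -> float:
    return 0.5 * special.erfc(z / math.sqrt(2.0))
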