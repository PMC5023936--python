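"""Exact conditional inference for 2x2 allele-count tables.

Conditional on both margins of the table

    =========  ============  ============
               minor allele  major allele
    cases      a             b
    controls   c             d
    =========  ============  ============

the case minor-allele count follows Fisher's noncentral hypergeometric
distribution with odds-ratio parameter psi.  Everything in this module is
built on direct enumeration of that distribution over its finite support,
carried out in log space so that tables with totals up to 10^6 are safe.

Three standard two-sided constructions are provided, following the exact
conditional-testing literature:

``minlike``
    sum of the probabilities of all outcomes no more likely than the one
    observed (the classical two-sided Fisher test);
``central``
    twice the smaller tail probability, capped at 1;
``blaker``
    sum of probabilities of outcomes whose smaller-tail ("acceptability")
    value does not exceed that of the observed outcome.

Confidence intervals are obtained by inverting the matching two-sided
test over psi, and the conditional maximum-likelihood odds ratio by
solving the conditional score equation; both use monotone bisection on
log(psi).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "P_METHODS",
    "support",
    "noncentral_hypergeom_logpmf",
    "fisher_exact_p",
    "conditional_mle_or",
    "exact_or_ci",
    "binomial_two_sided",
]

P_METHODS = ("minlike", "central", "blaker")

# Relative tie tolerance for "probability <= observed": outcomes whose
# probability exceeds the observed one by less than this relative amount
# still count as ties.  This is the convention used by exact-test
# implementations to make the minlike/blaker sums robust to roundoff.
TIE_REL = 1e-7

_MAX_TOTAL = 10**6


def _validate(a: int, b: int, c: int, d: int) -> None:
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
    if a + b + c + d > _MAX_TOTAL:
        raise ValueError(f"table total exceeds {_MAX_TOTAL}; enumeration refused")
    if (a + b == 0) or (c + d == 0):
        raise ValueError("both row margins (case and control totals) must be positive")
    # zero column margins are allowed: the support collapses to one point,
    # every two-sided p is 1 and the odds ratio is unidentifiable


def support(m1: int, m2: int, n: int) -> np.ndarray:
    """Feasible values of the (1,1) cell given row totals m1, m2 and column total n."""
    return np.arange(max(0, n - m2), min(n, m1) + 1)


@lru_cache(maxsize=200_000)
def _central_logcoef(m1: int, m2: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log binomial-product coefficients log[C(m1,k) C(m2,n-k)]."""
    k = support(m1, m2, n)
    logc = (
        gammaln(m1 + 1) - gammaln(k + 1) - gammaln(m1 - k + 1)
        + gammaln(m2 + 1) - gammaln(n - k + 1) - gammaln(m2 - n + k + 1)
    )
    return k, logc


def noncentral_hypergeom_logpmf(
    m1: int, m2: int, n: int, log_psi: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Log-pmf of the noncentral hypergeometric over its full support.

    ``log_psi = 0`` gives the central (ordinary) hypergeometric used by the
    null test; nonzero values tilt the distribution for CI inversion.
    """
    k, logc = _central_logcoef(m1, m2, n)
    logw = logc + k * log_psi
    return k, logw - logsumexp(logw)


@lru_cache(maxsize=200_000)
def _null_tables(m1: int, m2: int, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Support, null pmf and both cumulative tails for the central case."""
    k, logc = _central_logcoef(m1, m2, n)
    p = np.exp(logc - logsumexp(logc))
    return k, p, np.cumsum(p), np.cumsum(p[::-1])[::-1]


def _two_sided_p(p: np.ndarray, lower_cum: np.ndarray, upper_cum: np.ndarray,
                 idx: int, method: str) -> float:
    if method == "minlike":
        mass = float(p[p <= p[idx] * (1.0 + TIE_REL)].sum())
    elif method == "central":
        mass = 2.0 * min(float(lower_cum[idx]), float(upper_cum[idx]))
    elif method == "blaker":
        accept = np.minimum(lower_cum, upper_cum)
        mass = float(p[accept <= accept[idx] * (1.0 + TIE_REL)].sum())
    else:
        raise ValueError(f"unknown p-value method: {method!r}; expected one of {P_METHODS}")
    return min(1.0, mass)


def fisher_exact_p(
    a: int, b: int, c: int, d: int, method: str = "minlike", log_psi: float = 0.0
) -> float:
    """Exact two-sided p-value for a 2x2 table at odds ratio exp(log_psi).

    With the default ``log_psi = 0`` this is the usual Fisher-type null
    test; the ``method`` chooses the two-sided construction.
    """
    _validate(a, b, c, d)
    if log_psi == 0.0:
        k, p, lo_cum, up_cum = _null_tables(a + b, c + d, a + c)
    else:
        k, logpmf = noncentral_hypergeom_logpmf(a + b, c + d, a + c, log_psi)
        p = np.exp(logpmf)
        lo_cum, up_cum = np.cumsum(p), np.cumsum(p[::-1])[::-1]
    return _two_sided_p(p, lo_cum, up_cum, int(np.searchsorted(k, a)), method)


def _conditional_mean(m1: int, m2: int, n: int, log_psi: float) -> float:
    k, logpmf = noncentral_hypergeom_logpmf(m1, m2, n, log_psi)
    return float(np.sum(k * np.exp(logpmf)))


def conditional_mle_or(a: int, b: int, c: int, d: int, tol: float = 1e-10) -> float:
    """Conditional maximum-likelihood odds ratio.

    Solves the conditional score equation E_psi[X] = a by bisection on
    log(psi).  Observed counts at the support boundary give 0 or inf.
    """
    _validate(a, b, c, d)
    m1, m2, n = a + b, c + d, a + c
    k = support(m1, m2, n)
    if a == k[0] and a == k[-1]:
        return math.nan  # degenerate single-point support: psi unidentifiable
    if a == k[0]:
        return 0.0
    if a == k[-1]:
        return math.inf
    lo, hi = -1.0, 1.0
    while _conditional_mean(m1, m2, n, lo) > a:
        lo *= 2.0
        if lo < -750:  # pragma: no cover - unreachable for interior a
            return 0.0
    while _conditional_mean(m1, m2, n, hi) < a:
        hi *= 2.0
        if hi > 750:  # pragma: no cover
            return math.inf
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _conditional_mean(m1, m2, n, mid) < a:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def _tail_prob(m1: int, m2: int, n: int, a: int, log_psi: float, upper: bool) -> float:
    k, logpmf = noncentral_hypergeom_logpmf(m1, m2, n, log_psi)
    p = np.exp(logpmf)
    idx = int(np.searchsorted(k, a))
    return float(p[idx:].sum()) if upper else float(p[: idx + 1].sum())


def _bisect_log_psi(func, target: float, lo: float, hi: float, increasing: bool,
                    tol: float = 1e-8) -> float:
    """Find log_psi with func(log_psi) = target on a monotone stretch [lo, hi]."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        val = func(mid)
        if (val < target) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _expand_down(func, alpha: float, start: float) -> float | None:
    lo = start - 1.0
    while func(lo) >= alpha:
        lo -= 2.0
        if lo < -745:
            return None
    return lo


def _expand_up(func, alpha: float, start: float) -> float | None:
    hi = start + 1.0
    while func(hi) >= alpha:
        hi += 2.0
        if hi > 745:
            return None
    return hi


def exact_or_ci(
    a: int, b: int, c: int, d: int, level: float = 0.95, method: str = "minlike"
) -> tuple[float, float]:
    """Exact odds-ratio confidence interval by two-sided test inversion.

    The interval is {psi : p_method(table; psi) >= 1 - level}.  For
    ``central`` this reduces to equating each conditional tail to
    (1-level)/2; for ``minlike`` and ``blaker`` the two-sided p is
    inverted directly on each side of the conditional MLE (the p-value
    curve is treated as unimodal in psi, which holds for these
    constructions up to roundoff-scale ripples).  Observed counts at the
    support boundary yield 0 or inf endpoints.
    """
    _validate(a, b, c, d)
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if method not in P_METHODS:
        raise ValueError(f"unknown CI method: {method!r}; expected one of {P_METHODS}")
    alpha = 1.0 - level
    m1, m2, n = a + b, c + d, a + c
    k = support(m1, m2, n)
    if a == k[0] and a == k[-1]:
        return (0.0, math.inf)

    if method == "central":
        half = alpha / 2.0
        if a == k[0]:
            lower = 0.0
        else:
            f = lambda lp: _tail_prob(m1, m2, n, a, lp, upper=True)  # increasing in psi
            lo = _expand_down(f, half, 0.0)
            hi = 0.0
            while f(hi) < half:
                hi += 2.0
            lower = 0.0 if lo is None else math.exp(
                _bisect_log_psi(f, half, lo, hi, increasing=True)
            )
        if a == k[-1]:
            upper_ = math.inf
        else:
            g = lambda lp: _tail_prob(m1, m2, n, a, lp, upper=False)  # decreasing in psi
            hi = _expand_up(g, half, 0.0)
            lo = 0.0
            while g(lo) < half:
                lo -= 2.0
            upper_ = math.inf if hi is None else math.exp(
                _bisect_log_psi(g, half, lo, hi, increasing=False)
            )
        return (lower, upper_)

    # minlike / blaker: invert the two-sided p on each side of the CMLE.
    # The search pivots on a "center" where p >= alpha (near the CMLE the
    # p-value is close to 1); for boundary observations the center is found
    # by walking toward the boundary until p rises above alpha.
    pfun = lambda lp: fisher_exact_p(a, b, c, d, method=method, log_psi=lp)
    cmle = conditional_mle_or(a, b, c, d)
    if 0.0 < cmle < math.inf:
        center = math.log(cmle)
    else:
        center = 0.0
        step = -1.0 if cmle == 0.0 else 1.0
        while pfun(center) < alpha:
            center += step
            if abs(center) > 745:  # pragma: no cover
                break
    if a == k[0]:
        lower = 0.0
    else:
        lo = _expand_down(pfun, alpha, center)
        lower = 0.0 if lo is None else math.exp(
            _bisect_log_psi(pfun, alpha, lo, center, increasing=True)
        )
    if a == k[-1]:
        upper_ = math.inf
    else:
        hi = _expand_up(pfun, alpha, center)
        upper_ = math.inf if hi is None else math.exp(
            _bisect_log_psi(pfun, alpha, center, hi, increasing=False)
        )
    return (lower, upper_)


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided exact binomial p-value.

    Sums Binomial(n, p0) probabilities of all outcomes no more likely than
    the observed count ``k`` (same tie tolerance as the 2x2 tests).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0,1), got {p0}")
    x = np.arange(n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        + x * math.log(p0) + (n - x) * math.log1p(-p0)
    )
    p = np.exp(logpmf)
    return min(1.0, float(p[p <= p[k] * (1.0 + TIE_REL)].sum()))
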