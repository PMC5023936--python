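"""Population-level association statistics for a candidate risk variant.

Builds allele-count contingency tables from diploid genotype calls and
runs the exact conditional machinery from :mod:`vtescan.exact`, plus the
supporting checks used around a single-variant case-control result:
genotype-dosage LD r^2, a logistic confounding model fitted by IRLS,
Welch/exact covariate comparisons, and pairwise subcohort homogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import exact
from .io import MISSING

__all__ = [
    "AlleleCount",
    "TwoByTwoTable",
    "AssociationResult",
    "LDResult",
    "LogisticFit",
    "CovariateComparison",
    "allele_counts",
    "build_table",
    "fisher_exact_p",
    "odds_ratio",
    "exact_or_ci",
    "associate",
    "binomial_two_sided",
    "ld_r2",
    "logistic_fit",
    "compare_covariates",
    "subcohort_homogeneity",
]


@dataclass(frozen=True)
class AlleleCount:
    """Minor-allele count out of 2 x (non-missing subjects) total alleles."""

    minor: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.minor <= self.total):
            raise ValueError(f"need 0 <= minor <= total, got {self.minor}/{self.total}")

    @property
    def frequency(self) -> float:
        return self.minor / self.total

    @property
    def major(self) -> int:
        return self.total - self.minor


@dataclass(frozen=True)
class TwoByTwoTable:
    """Allele-count table: (a,b) case minor/major, (c,d) control minor/major."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    p_value: float
    p_method: str
    or_sample: float
    or_cmle: float
    ci: tuple[float, float]
    ci_level: float
    ci_method: str
    zero_cell: bool = False

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "p_method": self.p_method,
            "or_sample": self.or_sample,
            "or_cmle": self.or_cmle,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "zero_cell": self.zero_cell,
        }


@dataclass(frozen=True)
class LDResult:
    r_squared: float
    n_pairs: int


@dataclass
class LogisticFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    iterations: int
    n_used: int
    n_excluded: int
    separated: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": self.z, "p": self.p},
            index=self.names,
        )


@dataclass(frozen=True)
class CovariateComparison:
    name: str
    kind: str  # "continuous" | "categorical"
    statistic: float | None
    p_value: float | None
    case_summary: dict
    control_summary: dict
    note: str | None = None


# ---------------------------------------------------------------------------


def allele_counts(calls: Sequence[int] | np.ndarray) -> AlleleCount:
    """Count minor alleles over non-missing diploid calls at one site.

    Missing calls drop out of both numerator and denominator, so the
    total is 2 x (number of genotyped subjects).
    """
    arr = np.asarray(calls)
    keep = arr != MISSING
    if not keep.any():
        raise ValueError("all calls missing; allele counts undefined")
    kept = arr[keep]
    if not np.isin(kept, (0, 1, 2)).all():
        raise ValueError("calls must be in {0, 1, 2, missing}")
    return AlleleCount(minor=int(kept.sum()), total=2 * int(keep.sum()))


def build_table(case: AlleleCount, control: AlleleCount) -> TwoByTwoTable:
    """Assemble the case/control allele-count contingency table."""
    return TwoByTwoTable(a=case.minor, b=case.major, c=control.minor, d=control.major)


def fisher_exact_p(table: TwoByTwoTable, method: str = "minlike") -> float:
    """Exact two-sided p-value for association (see :func:`vtescan.exact.fisher_exact_p`)."""
    return exact.fisher_exact_p(*table.cells, method=method)


def odds_ratio(table: TwoByTwoTable, estimator: str = "sample") -> float:
    """Odds-ratio estimate: cross-product ``sample`` or conditional-MLE ``cmle``.

    A zero off-diagonal cell makes the sample OR 0 or inf (no continuity
    correction is applied).
    """
    a, b, c, d = table.cells
    if estimator == "sample":
        if b == 0 or c == 0:
            if a == 0 or d == 0:
                return math.nan
            return math.inf
        if a == 0 or d == 0:
            return 0.0
        return (a * d) / (b * c)
    if estimator == "cmle":
        return exact.conditional_mle_or(a, b, c, d)
    raise ValueError(f"unknown estimator: {estimator!r}")


def exact_or_ci(
    table: TwoByTwoTable, level: float = 0.95, method: str = "minlike"
) -> tuple[float, float]:
    return exact.exact_or_ci(*table.cells, level=level, method=method)


def associate(
    table: TwoByTwoTable,
    p_method: str = "minlike",
    ci_method: str = "minlike",
    level: float = 0.95,
) -> AssociationResult:
    """Full exact association summary for one 2x2 allele-count table."""
    a, b, c, d = table.cells
    return AssociationResult(
        p_value=fisher_exact_p(table, method=p_method),
        p_method=p_method,
        or_sample=odds_ratio(table, "sample"),
        or_cmle=odds_ratio(table, "cmle"),
        ci=exact_or_ci(table, level=level, method=ci_method),
        ci_level=level,
        ci_method=ci_method,
        zero_cell=(a == 0 or b == 0 or c == 0 or d == 0),
    )


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    return exact.binomial_two_sided(k, n, p0)


def ld_r2(calls_x: Sequence[int] | np.ndarray, calls_y: Sequence[int] | np.ndarray) -> LDResult:
    """Composite (genotype-dosage) LD r^2 between two sites.

    Squared Pearson correlation of alt-allele dosages over subjects with
    both calls non-missing.  Deterministic for unphased data, unlike
    EM-phased haplotype r^2.
    """
    x = np.asarray(calls_x, dtype=float)
    y = np.asarray(calls_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = (x != MISSING) & (y != MISSING)
    n = int(keep.sum())
    if n < 2:
        raise ValueError("need >= 2 subjects with both calls non-missing")
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined r²: variant monomorphic among complete pairs")
    r = np.corrcoef(xs, ys)[0, 1]
    return LDResult(r_squared=float(r * r), n_pairs=n)


# ---------------------------------------------------------------------------
# logistic regression (IRLS)

_SEPARATION_COEF = 30.0


def logistic_fit(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int] | np.ndarray,
    names: Sequence[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares, with per-coefficient Wald tests.

    Rows containing missing (NaN) predictors are excluded and counted in
    ``n_excluded``.  Convergence requires max |score| < ``tol``; runaway
    coefficients are reported as (quasi-)complete separation, in which
    case no estimates are returned.
    """
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y[~np.isnan(y)])) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    keep = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    n_excluded = int((~keep).sum())
    X, y = X[keep], y[keep]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    nonconst = np.ptp(X, axis=0) > 0
    if not nonconst[1 if add_intercept else 0:].all():
        raise ValueError("constant predictor other than the intercept")

    beta = np.zeros(p)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > _SEPARATION_COEF:
            separated = True
            break

    if separated or not converged:
        nan = np.full(p, np.nan)
        return LogisticFit(
            names=names, coef=nan, se=nan.copy(), z=nan.copy(), p=nan.copy(),
            converged=False, iterations=it, n_used=n, n_excluded=n_excluded,
            separated=separated,
        )

    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return LogisticFit(
        names=names, coef=beta, se=se, z=z, p=pvals,
        converged=True, iterations=it, n_used=n, n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# covariate comparisons and subcohort homogeneity


def compare_covariates(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    continuous: Sequence[str] = ("age", "height", "weight"),
    categorical: Sequence[str] = ("sex",),
) -> list[CovariateComparison]:
    """Per-covariate case/control comparisons.

    Continuous covariates: two-sided Welch (unequal-variance) t-test.
    Binary categorical covariates: exact minlike test on the 2x2 level
    count table.  Covariates constant in both arms are skipped with a
    note.
    """
    out: list[CovariateComparison] = []
    for name in continuous:
        x = cases[name].dropna().to_numpy(dtype=float)
        y = controls[name].dropna().to_numpy(dtype=float)
        case_s = {"n": len(x), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
        ctrl_s = {"n": len(y), "mean": float(np.mean(y)), "sd": float(np.std(y, ddof=1))}
        if np.ptp(np.concatenate([x, y])) == 0:
            out.append(CovariateComparison(name, "continuous", None, None, case_s, ctrl_s,
                                           note="constant in both arms; skipped"))
            continue
        t = scipy.stats.ttest_ind(x, y, equal_var=False)
        out.append(CovariateComparison(name, "continuous", float(t.statistic),
                                       float(t.pvalue), case_s, ctrl_s))
    for name in categorical:
        xc = cases[name].dropna()
        yc = controls[name].dropna()
        levels = sorted(set(xc.unique()) | set(yc.unique()))
        case_s = {str(l): int((xc == l).sum()) for l in levels}
        ctrl_s = {str(l): int((yc == l).sum()) for l in levels}
        if len(levels) < 2:
            out.append(CovariateComparison(name, "categorical", None, None, case_s, ctrl_s,
                                           note="constant in both arms; skipped"))
            continue
        if len(levels) > 2:
            raise ValueError(
                f"categorical covariate {name!r} has {len(levels)} levels; "
                "only binary covariates are supported"
            )
        a, b = case_s[str(levels[0])], case_s[str(levels[1])]
        c, d = ctrl_s[str(levels[0])], ctrl_s[str(levels[1])]
        p = exact.fisher_exact_p(a, b, c, d, method="minlike")
        out.append(CovariateComparison(name, "categorical", None, p, case_s, ctrl_s))
    return out


def subcohort_homogeneity(
    tables: Mapping[str, TwoByTwoTable],
) -> dict[str, dict[tuple[str, str], float]]:
    """Pairwise exact tests of allele-frequency homogeneity across subcohorts.

    For each arm (case row a/b; control row c/d) and each pair of
    subcohorts, tests whether the minor/major allele split differs
    between the two subcohorts.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 subcohorts for a homogeneity check")
    names = list(tables)
    result: dict[str, dict[tuple[str, str], float]] = {"case": {}, "control": {}}
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            ti, tj = tables[ni], tables[nj]
            result["case"][(ni, nj)] = exact.fisher_exact_p(
                ti.a, ti.b, tj.a, tj.b, method="minlike"
            )
            result["control"][(ni, nj)] = exact.fisher_exact_p(
                ti.c, ti.d, tj.c, tj.d, method="minlike"
            )
    return result
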