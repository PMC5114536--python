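"""Statistical kernel shared by every pipeline stage.

Each statistic is computed from its explicit formula; only distribution tail
probabilities (Student t, chi-squared, binomial) are delegated to
:mod:`scipy.stats`. All operations are pure and deterministic.

The kernel covers:

* Welch (or pooled) two-sample t test for differential abundance/expression.
* Benjamini–Hochberg step-up false-discovery-rate adjustment.
* Pearson and Spearman correlation with two-sided p values from the
  t transform of r.
* Fisher's combined probability test, chi2 = -2 * sum(ln p_i), referred to a
  chi-squared distribution with 2k degrees of freedom — the meta-analytic
  backbone of the per-group correlation network.
* Exact one-proportion (binomial) test.
* Ascending ranks with average ties, the primitive of the rank-sum
  regulator score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom as _binom
from scipy.stats import chi2 as _chi2
from scipy.stats import t as _t

from .errors import DegenerateInputError

__all__ = [
    "TestResult",
    "CombinedResult",
    "two_group_test",
    "bh_fdr",
    "fisher_combined",
    "pearson_corr",
    "spearman_corr",
    "one_proportion_test",
    "rank_ascending",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is the test statistic (t, r, rho, ...); ``p_value`` is
    two-sided unless the producing operation states otherwise. ``df`` is the
    degrees of freedom where applicable, ``n`` the effective sample size.
    """

    statistic: float
    p_value: float
    df: float | None = None
    n: int | None = None


@dataclass(frozen=True)
class CombinedResult:
    """Fisher's combined probability test over k independent p values."""

    chi2: float
    k: int
    df: int
    p_combined: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains missing values")
    return arr


def two_group_test(
    x, y, *, equal_var: bool = False, name: str | None = None
) -> TestResult:
    """Two-sample t test of ``x`` versus ``y``.

    Welch's unequal-variance statistic with Welch–Satterthwaite degrees of
    freedom by default; ``equal_var=True`` switches to the pooled-variance
    variant. The p value is two-sided.

    Raises
    ------
    ValueError
        if either sample has fewer than two observations.
    DegenerateInputError
        if both samples are constant (the statistic is undefined); the error
        message names ``name`` when given.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("two_group_test requires at least 2 observations per group")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        label = f" for feature {name!r}" if name else ""
        raise DegenerateInputError(
            f"both samples are constant{label}; t statistic undefined"
        )
    nx, ny = x.size, y.size
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = float(nx + ny - 2)
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    stat = (x.mean() - y.mean()) / se
    p = 2.0 * float(_t.sf(abs(stat), df))
    return TestResult(statistic=float(stat), p_value=min(p, 1.0), df=float(df), n=nx + ny)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q values).

    Returns adjusted values in the input order; ``q >= p`` elementwise and
    ``q`` is clipped to [0, 1]. An empty input yields an empty output.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1] with no missing entries")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def fisher_combined(p, *, zero_floor: float = 1e-300) -> CombinedResult:
    """Fisher's combined probability test.

    chi2 = -2 * sum(ln p_i) referred to the upper tail of a chi-squared
    distribution with 2k degrees of freedom. With k = 1 the combined p equals
    the input p. Exact zeros are clamped to ``zero_floor`` (with a warning)
    to keep the logarithm finite.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("fisher_combined requires at least one p value")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn(
            f"fisher_combined: clamping {int((p == 0).sum())} zero p value(s) "
            f"to {zero_floor:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.maximum(p, zero_floor)
    k = int(p.size)
    stat = float(-2.0 * np.log(p).sum())
    p_comb = float(_chi2.sf(stat, 2 * k))
    return CombinedResult(chi2=stat, k=k, df=2 * k, p_combined=p_comb)


def _corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient via the t transform."""
    df = n - 2
    denom = 1.0 - r * r
    if denom <= 0.0:
        return 0.0
    stat = r * np.sqrt(df / denom)
    return min(2.0 * float(_t.sf(abs(stat), df)), 1.0)


def pearson_corr(x, y) -> TestResult:
    """Pearson product-moment correlation with two-sided p value.

    Requires at least three paired observations and nonconstant vectors.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_corr requires at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    return TestResult(
        statistic=r, p_value=_corr_pvalue(r, x.size), df=float(x.size - 2), n=x.size
    )


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation: Pearson on tie-averaged ranks."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman_corr requires at least 3 paired observations")
    return pearson_corr(rank_ascending(x), rank_ascending(y))


def one_proportion_test(
    successes: int, n: int, p0: float, alternative: str = "two_sided"
) -> TestResult:
    """Exact binomial test of an observed proportion against ``p0``.

    ``alternative`` is one of ``two_sided``, ``greater``, ``less``. The
    two-sided p sums the probabilities of all outcomes no more likely than
    the observed one (the "minlike" convention of exact tests).
    """
    successes = int(successes)
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes ({successes}) must lie in [0, n={n}]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if alternative == "greater":
        p = float(_binom.sf(successes - 1, n, p0))
    elif alternative == "less":
        p = float(_binom.cdf(successes, n, p0))
    elif alternative == "two_sided":
        pmf = _binom.pmf(np.arange(n + 1), n, p0)
        observed = pmf[successes]
        p = float(pmf[pmf <= observed * (1.0 + 1e-9)].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(statistic=successes / n, p_value=min(p, 1.0), n=n)


def rank_ascending(values) -> np.ndarray:
    """Ascending ranks with average ties.

    The smallest value receives rank 1; tied values share the average of the
    ranks they cover, so the ranks always sum to n(n+1)/2. An empty input
    yields an empty output.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return v.copy()
    if np.isnan(v).any():
        raise ValueError("rank_ascending does not accept missing values")
    _, inverse, counts = np.unique(v, return_inverse=True, return_counts=True)
    upper = np.cumsum(counts).astype(float)
    avg = upper - (counts - 1) / 2.0
    return avg[inverse]
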