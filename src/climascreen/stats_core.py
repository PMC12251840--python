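"""Nonparametric and descriptive statistics used by the screening framework.

Thin, validated wrappers with fixed conventions:

* two-sided p-values throughout;
* mid-ranks for ties; the Kruskal–Wallis H carries the standard tie
  correction and the Mann–Whitney normal approximation uses the
  tie-adjusted variance with continuity correction;
* the Mann–Whitney p is exact (full enumeration) when both samples have
  n <= 50 and the pooled data is tie-free, otherwise asymptotic;
* quantiles use linear interpolation at position h = (n - 1) q on the
  sorted sample (numpy's "linear" rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "shapiro_wilk",
    "kruskal_wallis",
    "mann_whitney_u",
    "quantile",
    "linear_fit_r2",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test.

    ``statistic_name`` is one of W (Shapiro–Wilk), H (Kruskal–Wallis),
    U (Mann–Whitney) or R2 (linear goodness of fit); ``df`` is set for H
    (number of groups minus one) and R2 (n - 2); ``extras`` carries
    auxiliary fitted quantities such as the OLS slope and intercept.
    """

    statistic_name: str
    statistic: float
    p_value: float
    n_total: int
    df: Optional[int] = None
    extras: dict = field(default_factory=dict)


def _as_float_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if np.isnan(a).any():
        raise ValueError(f"{name} contains NaN")
    return a


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality test (valid for 3 <= n <= 5000)."""
    a = _as_float_array(values, "values")
    n = a.size
    if not 3 <= n <= 5000:
        raise ValueError(f"Shapiro–Wilk requires 3 <= n <= 5000, got n={n}")
    if np.ptp(a) == 0:
        raise ValueError("values are constant; W is undefined")
    w, p = sps.shapiro(a)
    return TestResult("W", float(w), float(p), n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis rank ANOVA across k groups; df = k - 1, p from the
    chi-squared upper tail, H tie-corrected."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [_as_float_array(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; H is undefined")
    h, p = sps.kruskal(*arrays)
    return TestResult("H", float(h), float(p), pooled.size, df=len(arrays) - 1)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Mann–Whitney U; U reported for the first sample.

    The exact two-sided p is computed when both n <= 50 with no pooled
    ties; otherwise the tie-corrected normal approximation with
    continuity correction is used.  A fully degenerate comparison (every
    pooled value identical) is perfectly symmetric: U = n_x n_y / 2, p = 1.
    """
    ax = _as_float_array(x, "x")
    ay = _as_float_array(y, "y")
    nx, ny = ax.size, ay.size
    pooled = np.concatenate([ax, ay])
    if np.ptp(pooled) == 0:
        return TestResult("U", nx * ny / 2.0, 1.0, nx + ny)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (nx <= 50 and ny <= 50 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(ax, ay, alternative="two-sided", method=method, use_continuity=True)
    return TestResult("U", float(res.statistic), float(min(res.pvalue, 1.0)), nx + ny,
                      extras={"method": method})


def quantile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation sample quantile (h = (n - 1) q)."""
    a = _as_float_array(values, "values")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q={q} outside [0, 1]")
    return float(np.quantile(a, q, method="linear"))


def linear_fit_r2(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """OLS fit of y on x; statistic is the coefficient of determination R²,
    p is the two-sided slope test, slope/intercept in ``extras``."""
    ax = _as_float_array(x, "x")
    ay = _as_float_array(y, "y")
    if ax.size != ay.size:
        raise ValueError("x and y must have equal length")
    if ax.size < 3:
        raise ValueError("need n >= 3 points")
    if np.ptp(ax) == 0:
        raise ValueError("x is constant; the fit is undefined")
    fit = sps.linregress(ax, ay)
    return TestResult(
        "R2",
        float(fit.rvalue**2),
        float(fit.pvalue),
        ax.size,
        df=ax.size - 2,
        extras={"slope": float(fit.slope), "intercept": float(fit.intercept)},
    )
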