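"""Inferential statistics shared by the other stages.

Thin, contract-enforcing wrappers around scipy and statsmodels: a classical
(pooled-variance) two-group Student's t test, Pearson correlation with the
t-transform p-value, Benjamini-Hochberg step-up FDR adjustment, and a
two-factor ANOVA with type-II sums of squares. All wrappers validate their
inputs and raise typed errors on degenerate data instead of returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupContrastResult",
    "CorrelationResult",
    "AnovaEffect",
    "DegenerateDataError",
    "InsufficientDataError",
    "students_t_test",
    "pearson_correlation",
    "bh_fdr",
    "two_way_anova",
]


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined (zero variance, constant data)."""


class InsufficientDataError(ValueError):
    """Raised when there are too few observations to form the statistic."""


@dataclass(frozen=True)
class GroupContrastResult:
    """Two-group location contrast."""

    statistic: float
    p_value: float
    group_means: tuple[float, float]
    df: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    p_value: float
    df: float
    sum_sq: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def students_t_test(x, y, two_sided: bool = True, welch: bool = False) -> GroupContrastResult:
    """Two-group Student's t test (pooled variance by default).

    Parameters
    ----------
    x, y
        Observations of the two groups.
    two_sided
        If False, tests the one-sided alternative mean(x) > mean(y).
    welch
        If True, uses the Welch (unequal-variance) statistic instead of the
        classical pooled-variance form.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    n1, n2 = xa.size, ya.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(f"each group needs n >= 2 (got {n1}, {n2})")
    s1, s2 = xa.var(ddof=1), ya.var(ddof=1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if pooled == 0.0:
        raise DegenerateDataError("zero pooled variance: all observations identical")
    alternative = "two-sided" if two_sided else "greater"
    res = _sps.ttest_ind(xa, ya, equal_var=not welch, alternative=alternative)
    df = float(res.df) if welch else float(n1 + n2 - 2)
    return GroupContrastResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_means=(float(xa.mean()), float(ya.mean())),
        df=df,
    )


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t transform
    ``r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 points (got {n})")
    if xa.var() == 0.0 or ya.var() == 0.0:
        raise DegenerateDataError("correlation undefined: zero variance input")
    res = _sps.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved.

    adj_i = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = _as_1d(p_values, "p_values")
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_way_anova(values, factor_a, factor_b) -> dict[str, AnovaEffect]:
    """Two-factor ANOVA with type-II sums of squares.

    Returns effects keyed 'factor_a', 'factor_b', 'interaction', plus a
    'residual' entry carrying the residual df and SS (F and p are NaN there).
    Works for balanced and unbalanced designs with >= 1 residual df.
    """
    v = _as_1d(values, "values")
    a = np.asarray(factor_a, dtype=object).ravel()
    b = np.asarray(factor_b, dtype=object).ravel()
    if not (v.size == a.size == b.size):
        raise ValueError("values and factor labels must have equal length")
    if v.size and np.ptp(v) == 0.0:
        raise DegenerateDataError("all values equal: F statistics undefined")
    df = pd.DataFrame({"value": v, "fa": a.astype(str), "fb": b.astype(str)})
    model = ols("value ~ C(fa) + C(fb) + C(fa):C(fb)", data=df).fit()
    if model.df_resid < 1:
        raise InsufficientDataError("zero residual degrees of freedom")
    table = anova_lm(model, typ=2)
    key_map: Mapping[str, str] = {
        "C(fa)": "factor_a",
        "C(fb)": "factor_b",
        "C(fa):C(fb)": "interaction",
        "Residual": "residual",
    }
    out: dict[str, AnovaEffect] = {}
    for row_name, row in table.iterrows():
        name = key_map.get(str(row_name), str(row_name))
        out[name] = AnovaEffect(
            name=name,
            F=float(row["F"]),
            p_value=float(row["PR(>F)"]),
            df=float(row["df"]),
            sum_sq=float(row["sum_sq"]),
        )
    return out
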