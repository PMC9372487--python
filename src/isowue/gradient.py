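"""Site-level gradient analysis: regressions on aridity, correlation
tables, slope-homogeneity tests, and variation partitioning between
predictor sets.

Variation partitioning follows the standard nested-regression scheme: with
R2(W), R2(N) and R2(W+N) the coefficients of determination of the water
set, the nutrient set and their union, the unique water fraction is
R2(W+N) - R2(N), the unique nutrient fraction R2(W+N) - R2(W), the shared
fraction R2(W) + R2(N) - R2(W+N) and the unexplained remainder
1 - R2(W+N).  With raw R2 the four fractions sum to one identically; with
adjusted R2 (the conventional report when predictor sets differ in size)
unique and shared fractions can be slightly negative and are reported as
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "RegressionFit",
    "PartitionFractions",
    "linear_regression",
    "pearson_table",
    "compare_slopes",
    "variation_partition",
]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares fit of y on a single predictor."""

    slope: float
    intercept: float
    r2: float
    p: float
    se_slope: float
    n: int


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Simple linear regression; p-value from the two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have equal length")
    if x.size < 3:
        raise DomainError("need n >= 3")
    if np.ptp(x) == 0:
        raise DomainError("constant predictor: regression undefined")
    if np.ptp(y) == 0:
        # constant response: flat line fits exactly, no explainable variance
        return RegressionFit(
            slope=0.0, intercept=float(y[0]), r2=0.0, p=1.0, se_slope=0.0,
            n=int(x.size),
        )
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        se_slope=float(res.stderr),
        n=int(x.size),
    )


def pearson_table(
    site_stats: pd.DataFrame,
    env: pd.DataFrame,
    stat_cols: Sequence[str] = ("iWUE_mean", "iWUE_cv"),
    env_cols: Sequence[str] = ("SM", "VPD", "SOC_TN"),
) -> pd.DataFrame:
    """Pearson r and two-sided p for each site statistic against each
    environmental variable; rows are environment variables, columns carry
    (statistic, r) and (statistic, p).  Cells with a constant column are
    NaN.  Tables are aligned on ``site_id``.
    """
    merged = site_stats.merge(env, on="site_id", validate="one_to_one")
    if len(merged) < 3:
        raise DomainError("need at least 3 complete site rows")
    out = {}
    for sc in stat_cols:
        rs, ps = [], []
        for ec in env_cols:
            a = merged[sc].to_numpy(float)
            b = merged[ec].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rs.append(np.nan)
                ps.append(np.nan)
            else:
                r, p = stats.pearsonr(a, b)
                rs.append(float(r))
                ps.append(float(p))
        out[(sc, "r")] = rs
        out[(sc, "p")] = ps
    return pd.DataFrame(out, index=pd.Index(env_cols, name="env_var"))


def compare_slopes(groups: Sequence[tuple[Sequence[float], Sequence[float]]]):
    """Homogeneity-of-slopes F-test across groups.

    Fits the pooled model y ~ x * group and tests the group-by-predictor
    interaction.  Returns (F, p).
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups to compare slopes")
    frames = []
    for gi, (x, y) in enumerate(groups):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.size < 3 or np.ptp(x) == 0:
            raise DomainError("each group needs n >= 3 and a non-constant predictor")
        frames.append(pd.DataFrame({"x": x, "y": y, "g": f"g{gi}"}))
    df = pd.concat(frames, ignore_index=True)

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    fit = smf.ols("y ~ x * C(g)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(fit, typ=2)
    row = table.loc["x:C(g)"]
    return float(row["F"]), float(row["PR(>F)"])


@dataclass(frozen=True)
class PartitionFractions:
    unique_water: float
    unique_nutrient: float
    shared: float
    unexplained: float
    r2_kind: str


def _r2(X: np.ndarray, y: np.ndarray, adjusted: bool) -> float:
    n = len(y)
    Xc = np.column_stack([np.ones(n), X])
    if np.linalg.cond(Xc) > 1e10:
        warnings.warn("ill-conditioned predictor set; fit uses pseudoinverse")
    beta, _, _, _ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise DomainError("constant response: R2 undefined")
    r2 = 1.0 - float(resid @ resid) / tss
    if adjusted:
        p = X.shape[1]
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2


def variation_partition(
    y: Sequence[float],
    X_water: np.ndarray,
    X_nutrient: np.ndarray,
    r2_kind: str = "adjusted",
) -> PartitionFractions:
    """Partition variance of a site statistic between two predictor sets."""
    if r2_kind not in {"raw", "adjusted"}:
        raise DomainError(f"unknown r2_kind: {r2_kind!r}")
    y = np.asarray(y, dtype=float)
    Xw = np.atleast_2d(np.asarray(X_water, float))
    Xn = np.atleast_2d(np.asarray(X_nutrient, float))
    if Xw.shape[0] != len(y):
        Xw = Xw.T
    if Xn.shape[0] != len(y):
        Xn = Xn.T
    p_total = Xw.shape[1] + Xn.shape[1]
    if len(y) <= p_total + 1:
        raise DomainError("need n > combined predictor count + 1")
    adj = r2_kind == "adjusted"
    r2w = _r2(Xw, y, adj)
    r2n = _r2(Xn, y, adj)
    r2b = _r2(np.column_stack([Xw, Xn]), y, adj)
    return PartitionFractions(
        unique_water=r2b - r2n,
        unique_nutrient=r2b - r2w,
        shared=r2w + r2n - r2b,
        unexplained=1.0 - r2b,
        r2_kind=r2_kind,
    )
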