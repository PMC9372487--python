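"""Per-site community distribution statistics of a leaf trait.

Frequency-distribution characteristics (mean, variance, SD, CV, range,
skewness, kurtosis), Shapiro-Wilk normality, one-way ANOVA with Duncan's
multiple range test, and the within- versus among-site variance split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InapplicableTestError

__all__ = [
    "CommunityDistribution",
    "AnovaResult",
    "distribution_characteristics",
    "shapiro_wilk",
    "one_way_anova",
    "duncan_posthoc",
    "within_among_partition",
    "site_distribution_table",
]


@dataclass(frozen=True)
class CommunityDistribution:
    """Distribution characteristics of one site's trait values.

    Skewness is the bias-corrected sample skewness G1 and kurtosis the
    bias-corrected excess kurtosis G2 (the conventions of mainstream
    commercial statistics packages).  CV is in percent.  Fields that need
    n >= 2 (or n >= 3/4 for shape statistics) are NaN below those sizes and
    noted in ``flags``.
    """

    site_id: Optional[str]
    n: int
    mean: float
    variance: float
    sd: float
    cv: float
    range: float
    skewness: float
    kurtosis: float
    shapiro_W: float
    shapiro_p: float
    flags: str = ""


def distribution_characteristics(
    values: Sequence[float], site_id: Optional[str] = None
) -> CommunityDistribution:
    """Frequency-distribution characteristics of one community sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("empty sample")
    if not np.all(np.isfinite(x)):
        raise DomainError("non-finite trait value")
    n = int(x.size)
    flags = []
    mean = float(x.mean())
    if n >= 2:
        var = float(x.var(ddof=1))
        sd = float(np.sqrt(var))
        rng_ = float(x.max() - x.min())
        if mean != 0:
            cv = 100.0 * sd / mean
        else:
            cv = np.nan
            flags.append("cv_undefined_zero_mean")
    else:
        var = sd = rng_ = cv = np.nan
        flags.append("n1_moments_missing")
    skew = float(stats.skew(x, bias=False)) if n >= 3 and sd > 0 else np.nan
    kurt = (
        float(stats.kurtosis(x, fisher=True, bias=False))
        if n >= 4 and sd > 0
        else np.nan
    )
    if n >= 3 and sd == 0:
        flags.append("constant_sample_shape_undefined")
    try:
        W, p = shapiro_wilk(x)
    except InapplicableTestError:
        W = p = np.nan
        flags.append("shapiro_inapplicable")
    return CommunityDistribution(
        site_id=site_id,
        n=n,
        mean=mean,
        variance=var,
        sd=sd,
        cv=cv,
        range=rng_,
        skewness=skew,
        kurtosis=kurt,
        shapiro_W=W,
        shapiro_p=p,
        flags=";".join(flags),
    )


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (delegates to scipy).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise InapplicableTestError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise InapplicableTestError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from raw group samples."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise DomainError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise DomainError("every group needs at least 2 observations")
    allx = np.concatenate(gs)
    grand = allx.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in gs))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b = len(gs) - 1
    df_w = allx.size - len(gs)
    if ss_within == 0 and ss_between == 0:
        raise DomainError("zero total variance: F undefined")
    if ss_within == 0:
        return AnovaResult(np.inf, 0.0, ss_between, ss_within, df_b, df_w)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, ss_between, ss_within, df_b, df_w)


def duncan_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Duncan's multiple range test at protection level alpha.

    Means are sorted and ranges tested sequentially: a span of p ordered
    means is declared homogeneous when its extremes differ by less than the
    least significant range R_p = q(1-(1-alpha)^(p-1); p, df) *
    sqrt(MS_within / n_h), with q the studentized-range quantile evaluated
    numerically and n_h the harmonic mean of the span's group sizes; spans
    inside a homogeneous span are never subdivided.  Groups sharing a
    letter in the returned mapping are not significantly separated.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(gs))]
    anova = one_way_anova(gs)
    if not np.isfinite(anova.F):
        # Zero within-group variance: every distinct mean separates.
        order = np.argsort([-g.mean() for g in gs])
        letters = {}
        seen_means: dict[float, str] = {}
        for rank, idx in enumerate(order):
            m = gs[idx].mean()
            if m not in seen_means:
                seen_means[m] = chr(ord("a") + len(seen_means))
            letters[labels[idx]] = seen_means[m]
        return letters

    ms_within, df_w = anova.ms_within, anova.df_within
    order = np.argsort([-g.mean() for g in gs])  # descending means
    means = np.array([gs[i].mean() for i in order])
    sizes = np.array([gs[i].size for i in order])
    k = len(gs)

    def lsr(i: int, j: int) -> float:
        p = j - i + 1
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, p, df_w)
        n_h = stats.hmean(sizes[i : j + 1])
        return float(q * np.sqrt(ms_within / n_h))

    homogeneous: list[tuple[int, int]] = []

    def test_range(i: int, j: int) -> None:
        if i >= j:
            return
        if means[i] - means[j] < lsr(i, j):
            homogeneous.append((i, j))
            return
        test_range(i, j - 1)
        test_range(i + 1, j)

    test_range(0, k - 1)
    # Maximal homogeneous intervals, plus singletons for uncovered groups.
    maximal = [
        (i, j)
        for (i, j) in sorted(set(homogeneous))
        if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in homogeneous)
    ]
    covered = {r for i, j in maximal for r in range(i, j + 1)}
    intervals = sorted(maximal + [(r, r) for r in range(k) if r not in covered])
    letter_of_interval = {iv: chr(ord("a") + idx) for idx, iv in enumerate(intervals)}
    out = {}
    for rank, orig in enumerate(order):
        ls = [letter_of_interval[iv] for iv in intervals if iv[0] <= rank <= iv[1]]
        out[labels[orig]] = "".join(ls)
    return out


def within_among_partition(records) -> tuple[float, float]:
    """Split total sum of squares into within-site and among-site percent.

    ``records`` is an iterable of (site_id, value) pairs or a DataFrame
    with columns ``site_id`` and a single value column.  Returns
    (pct_within, pct_among); the two sum to 100.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        value_col = [c for c in df.columns if c != "site_id"][0]
        site, val = df["site_id"].to_numpy(), df[value_col].to_numpy(float)
    else:
        pairs = list(records)
        site = np.array([p[0] for p in pairs])
        val = np.array([p[1] for p in pairs], dtype=float)
    if len(np.unique(site)) < 2:
        raise DomainError("need at least 2 sites")
    grand = val.mean()
    ss_total = float(((val - grand) ** 2).sum())
    if ss_total == 0:
        raise DomainError("zero total sum of squares: partition undefined")
    ss_within = 0.0
    for s in np.unique(site):
        v = val[site == s]
        ss_within += float(((v - v.mean()) ** 2).sum())
    pct_within = 100.0 * ss_within / ss_total
    return pct_within, 100.0 - pct_within


def site_distribution_table(
    df: pd.DataFrame, value_col: str = "iWUE", site_col: str = "site_id"
) -> pd.DataFrame:
    """One CommunityDistribution row per site, as a DataFrame."""
    rows = []
    for site, sub in df.groupby(site_col, sort=True):
        cd = distribution_characteristics(sub[value_col].to_numpy(), site_id=site)
        rows.append(cd.__dict__)
    return pd.DataFrame(rows)
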