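"""Two-factor decomposition of trait variance: species, site, interaction.

Transect surveys are inherently unbalanced — each species occupies only a
stretch of sites — so main-effect sums of squares are computed as partial
(Type II) SS by nested least-squares model comparisons, which remain
well-defined on rank-deficient designs with missing cells; sequential
(Type I) SS is available behind a flag.  Percent contributions are shares
of the explained (model) SS, so the three terms sum to 100 whenever the
interaction is estimable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["VarianceComponents", "partition_species_site"]


@dataclass
class VarianceComponents:
    pct_species: float
    pct_site: float
    pct_interaction: float  # NaN when the interaction is not estimable
    ss_table: pd.DataFrame
    model_r2: float
    interaction_estimable: bool


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def partition_species_site(
    records: pd.DataFrame,
    response: str = "iWUE",
    species_col: str = "species_id",
    site_col: str = "site_id",
    ss_type: str = "partial",
) -> VarianceComponents:
    """Partition trait variance into species, site and interaction shares.

    Parameters
    ----------
    records : DataFrame
        Long-format table with one row per observation.
    ss_type : {"partial", "sequential"}
        Partial (Type II) enters each main effect after the other;
        sequential (Type I) enters species, then site.  The interaction is
        always entered last.  On balanced designs the two coincide.

    Notes
    -----
    The interaction SS is the RSS drop from the additive model to the
    cell-means model.  It is estimable only when the observed cells supply
    more degrees of freedom than the additive model uses; otherwise a
    two-term partition is returned with ``pct_interaction`` = NaN.  Cells
    with a single observation contribute to main effects but supply no
    within-cell error.
    """
    if ss_type not in {"partial", "sequential"}:
        raise DomainError(f"unknown ss_type: {ss_type!r}")
    y = records[response].to_numpy(dtype=float)
    sp = pd.Categorical(records[species_col])
    si = pd.Categorical(records[site_col])
    if len(sp.categories) < 2 or len(si.categories) < 2:
        raise DomainError("need at least 2 species and 2 sites")
    n = len(y)

    ones = np.ones((n, 1))
    Xsp = np.column_stack([ones, pd.get_dummies(sp, dtype=float).to_numpy()])
    Xsi = np.column_stack([ones, pd.get_dummies(si, dtype=float).to_numpy()])
    Xadd = np.column_stack([Xsp, pd.get_dummies(si, dtype=float).to_numpy()])
    cell = pd.Categorical(
        pd.Series(sp.codes).astype(str) + ":" + pd.Series(si.codes).astype(str)
    )
    Xcell = np.column_stack([ones, pd.get_dummies(cell, dtype=float).to_numpy()])

    ss_total = float(((y - y.mean()) ** 2).sum())
    rss_null = ss_total
    rss_sp, rank_sp = _rss(Xsp, y)
    rss_si, rank_si = _rss(Xsi, y)
    rss_add, rank_add = _rss(Xadd, y)
    rss_cell, rank_cell = _rss(Xcell, y)

    if ss_type == "partial":
        ss_species = rss_si - rss_add
        ss_site = rss_sp - rss_add
    else:
        ss_species = rss_null - rss_sp
        ss_site = rss_sp - rss_add
    df_species = rank_add - rank_si if ss_type == "partial" else rank_sp - 1
    df_site = rank_add - rank_sp

    df_interaction = rank_cell - rank_add
    interaction_estimable = df_interaction > 0
    ss_interaction = rss_add - rss_cell if interaction_estimable else np.nan

    full_rss = rss_cell if interaction_estimable else rss_add
    model_r2 = 1.0 - full_rss / ss_total if ss_total > 0 else np.nan

    terms = [
        ("species", ss_species, df_species),
        ("site", ss_site, df_site),
        ("interaction", ss_interaction, df_interaction),
        ("residual", full_rss, n - (rank_cell if interaction_estimable else rank_add)),
        ("total", ss_total, n - 1),
    ]
    ss_table = pd.DataFrame(terms, columns=["term", "ss", "df"])

    explained_terms = [ss_species, ss_site] + (
        [ss_interaction] if interaction_estimable else []
    )
    explained = float(np.sum(explained_terms))
    if explained <= 0:
        raise DomainError("no explained variance: partition undefined")
    pct = [100.0 * s / explained for s in (ss_species, ss_site)]
    pct_int = (
        100.0 * ss_interaction / explained if interaction_estimable else np.nan
    )
    return VarianceComponents(
        pct_species=pct[0],
        pct_site=pct[1],
        pct_interaction=pct_int,
        ss_table=ss_table,
        model_r2=model_r2,
        interaction_estimable=interaction_estimable,
    )
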