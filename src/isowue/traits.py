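"""Leaf-trait spectrum analysis: PCA of {iWUE, Delta18O, SLA, N_area} and
regressions of iWUE on the axis scores of the trait-only ordination.

The four traits carry incommensurable units, so the default ordination is
of the correlation matrix (standardized traits); eigenvalues then sum to
the number of traits.  Loading signs are fixed deterministically: each
loading column is flipped so its largest-magnitude element is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .gradient import RegressionFit, linear_regression

__all__ = ["PCAResult", "pca", "pca_excluding", "iwue_vs_axis_scores"]

TRAIT_COLUMNS = ("iWUE", "big_delta18O", "SLA", "N_area")


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # traits x axes
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # percent per axis
    scores: pd.DataFrame  # records x axes
    standardized: bool


def pca(trait_table: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """Principal component analysis of a records-by-traits table.

    Rows with any missing value are dropped listwise.  Decomposes the
    correlation matrix when ``standardize`` (default) or the covariance
    matrix otherwise; scores are the centered (and scaled) data projected
    on the loadings.
    """
    df = trait_table.dropna(axis=0, how="any")
    if df.shape[1] < 2:
        raise DomainError("need at least 2 traits")
    if df.shape[0] < 3:
        raise DomainError("need at least 3 complete records")
    X = df.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    Xc = X - mu
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            bad = list(df.columns[zero])
            raise DomainError(f"constant trait(s) cannot be standardized: {bad}")
        Xc = Xc / sd
    S = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # Deterministic sign: largest-|loading| entry of each column positive.
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    axes = [f"Axis{j + 1}" for j in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=df.columns, columns=axes)
    scores = pd.DataFrame(Xc @ eigvec, index=df.index, columns=axes)
    var_expl = 100.0 * eigval / eigval.sum()
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigval,
        variance_explained=var_expl,
        scores=scores,
        standardized=standardize,
    )


def pca_excluding(
    trait_table: pd.DataFrame, column: str = "iWUE", standardize: bool = True
) -> PCAResult:
    """Ordination of the trait table with one column (default iWUE) left
    out — the trait-only spectrum whose axis scores iWUE is regressed on."""
    if column not in trait_table.columns:
        raise DomainError(f"column {column!r} not in trait table")
    return pca(trait_table.drop(columns=[column]), standardize=standardize)


def iwue_vs_axis_scores(
    scores: pd.DataFrame, iwue: Sequence[float]
) -> dict[str, RegressionFit]:
    """Simple regression of iWUE on each ordination axis score."""
    iwue = np.asarray(iwue, dtype=float)
    if len(iwue) != len(scores):
        raise DomainError("iwue and scores must align row-wise")
    return {
        axis: linear_regression(scores[axis].to_numpy(), iwue)
        for axis in scores.columns
    }
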