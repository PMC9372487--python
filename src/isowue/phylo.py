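"""Phylogenetic signal of a continuous trait: Blomberg's K with a
permutation test.

K compares the observed ratio of the trait's cross-species mean squared
error to its phylogenetically corrected counterpart against the value that
ratio takes in expectation under Brownian-motion evolution on the same
tree; K = 1 for Brownian traits, K -> 0 as signal vanishes.  Significance
is assessed by shuffling trait values across tips and asking how often the
permuted phylogenetic MSE is as small as the observed one (small MSE =
strong signal), with the add-one convention so p is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import DomainError, ValidationError

__all__ = ["PhyloSignalResult", "vcv_matrix", "blomberg_k", "phylo_signal_test"]


@dataclass(frozen=True)
class PhyloSignalResult:
    """Outcome of a phylogenetic-signal randomization test."""

    K: float
    p: float
    n_permutations: int
    n_tips_used: int
    seed: int


def vcv_matrix(tree: dendropy.Tree, min_terminal_frac: float = 1e-8):
    """Shared-path-length (phylogenetic covariance) matrix of a tree.

    Entry (i, j) is the branch length shared by the root-to-tip paths of
    tips i and j; the diagonal holds root-to-tip distances.  Zero-length
    terminal branches are raised to ``min_terminal_frac`` times the tree
    height so the matrix stays invertible.

    Returns
    -------
    (labels, C) : list of str, ndarray
    """
    tree = tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise DomainError("tree must have at least 2 tips")
    height = max(lf.distance_from_root() for lf in leaves)
    if height <= 0:
        raise DomainError("tree has no positive branch lengths")
    eps = min_terminal_frac * height
    for lf in leaves:
        if lf.edge.length is None or lf.edge.length < eps:
            lf.edge.length = eps

    labels = [lf.taxon.label for lf in leaves]
    depth = {id(lf): lf.distance_from_root() for lf in leaves}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    C = np.empty((n, n))
    for i, li in enumerate(leaves):
        C[i, i] = depth[id(li)]
        for j in range(i + 1, n):
            lj = leaves[j]
            d = pdm.patristic_distance(li.taxon, lj.taxon)
            C[i, j] = C[j, i] = 0.5 * (depth[id(li)] + depth[id(lj)] - d)
    return labels, C


def _match(tree: dendropy.Tree, trait: Mapping[str, float]):
    labels, C = vcv_matrix(tree)
    present = [lab for lab in labels if lab in trait]
    missing = len(labels) - len(present)
    if missing:
        warnings.warn(
            f"{missing} tree tips lack trait values and were dropped",
            stacklevel=3,
        )
    if len(present) < 4:
        raise DomainError("need at least 4 matched tips for Blomberg's K")
    idx = [labels.index(lab) for lab in present]
    x = np.array([float(trait[lab]) for lab in present])
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite trait value")
    return x, C[np.ix_(idx, idx)]


def _k_and_mse(x: np.ndarray, C: np.ndarray):
    n = len(x)
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological trees
        raise DomainError("ill-conditioned phylogenetic covariance matrix") from exc
    w = cho_solve(cf, np.ones(n))  # C^-1 1
    denom = w.sum()  # 1' C^-1 1
    ahat = (w @ x) / denom
    r = x - ahat
    mse0 = r @ r / (n - 1)
    mse = r @ cho_solve(cf, r) / (n - 1)
    expected = (np.trace(C) - n / denom) / (n - 1)
    K = (mse0 / mse) / expected
    return K, mse, cf, denom


def blomberg_k(tree: dendropy.Tree, trait: Mapping[str, float]) -> float:
    """Blomberg's K for a tip trait on a rooted tree with branch lengths.

    With C the shared-path-length matrix, the phylogenetic mean is
    a_hat = (1'C^-1 x)/(1'C^-1 1), MSE0 = (x-a_hat)'(x-a_hat)/(n-1) and
    MSE = (x-a_hat)'C^-1(x-a_hat)/(n-1); K is the observed MSE0/MSE scaled
    by its Brownian expectation [tr(C) - n/(1'C^-1 1)]/(n-1).
    """
    x, C = _match(tree, trait)
    K, _, _, _ = _k_and_mse(x, C)
    return float(K)


def phylo_signal_test(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    n_permutations: int = 999,
    seed: int = 0,
) -> PhyloSignalResult:
    """Permutation test of phylogenetic signal for a tip trait.

    Trait values are shuffled across tips ``n_permutations`` times; the
    one-sided p-value is the add-one-smoothed fraction of permutations
    whose phylogenetically corrected MSE is at most the observed MSE.
    """
    if n_permutations < 99:
        raise DomainError("use at least 99 permutations")
    x, C = _match(tree, trait)
    n = len(x)
    K, mse_obs, cf, denom = _k_and_mse(x, C)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(x) for _ in range(n_permutations)], axis=1)
    w = cho_solve(cf, np.ones(n))
    ahat = (w @ perms) / denom  # per-column phylogenetic mean
    R = perms - ahat  # (n, n_permutations)
    mse_perm = np.einsum("ij,ij->j", R, cho_solve(cf, R)) / (n - 1)
    p = (1 + int(np.sum(mse_perm <= mse_obs))) / (1 + n_permutations)
    return PhyloSignalResult(
        K=float(K),
        p=float(p),
        n_permutations=n_permutations,
        n_tips_used=n,
        seed=seed,
    )
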