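"""Blomberg's K phylogenetic signal with a tip-permutation test.

K compares the observed ratio of trait variance (around the phylogenetic
GLS mean) to its phylogenetically corrected counterpart against the value
expected under Brownian motion on the given tree. K ~ 1 indicates
Brownian-like signal, K ~ 0 a trait independent of phylogeny. Writing C
for the tip variance-covariance matrix implied by the tree (shared
root-to-MRCA branch length for each tip pair) and x for the trait vector:

    a_hat = (1' C^-1 1)^-1 (1' C^-1 x)
    MSE0  = (x - a_hat)'        (x - a_hat) / (n - 1)
    MSE   = (x - a_hat)' C^-1   (x - a_hat) / (n - 1)
    K     = (MSE0 / MSE) / ( [tr(C) - n / (1' C^-1 1)] / (n - 1) )

Significance is assessed by shuffling trait values across tips: the
permutation p-value is (1 + #{K_perm >= K_obs}) / (n_perm + 1), so it is
bounded below by 1/(n_perm + 1) and never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import InvalidParameterError, UndefinedStatisticError

__all__ = [
    "PhyloSignalResult",
    "vcv_from_tree",
    "blomberg_k",
    "perm_test_k",
    "load_tree",
]


@dataclass(frozen=True)
class PhyloSignalResult:
    k: float
    p_perm: float
    n_perm: int


def load_tree(path_or_string: str, from_path: bool = True) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths."""
    kwargs = {"path": path_or_string} if from_path else {"data": path_or_string}
    return dendropy.Tree.get(schema="newick", **kwargs)


def vcv_from_tree(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Tip variance-covariance matrix implied by a rooted tree.

    ``C[i, j]`` is the branch length shared from the root down to the most
    recent common ancestor of tips i and j; the diagonal holds the
    root-to-tip path lengths. Zero-length terminal branches would make C
    singular and are perturbed by 1e-8 x tree depth (with a warning).

    Returns the matrix together with the tip labels, in matrix order.
    """
    leaves = tree.leaf_nodes()
    n = len(leaves)
    if n < 3:
        raise InvalidParameterError("tree must have at least 3 tips")
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != n:
        raise InvalidParameterError("tip labels must be unique")
    index = {id(lf): i for i, lf in enumerate(leaves)}

    # Depth of every node below the root (edge lengths default to 0).
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    C = np.zeros((n, n))
    # Post-order sweep: tips under each child subtree of a node have that
    # node as their MRCA when paired across subtrees.
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            C[i, i] = depth[id(node)]
            below[id(node)] = [i]
            continue
        child_sets = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    C[i, child_sets[b]] = d
                    C[child_sets[b], i] = d
        below[id(node)] = [i for s in child_sets for i in s]

    tip_depths = np.diag(C).copy()
    max_depth = float(tip_depths.max())
    if max_depth <= 0:
        raise UndefinedStatisticError("tree has zero total depth; C is singular")
    internal_depths = np.array(
        [depth[id(lf.parent_node)] for lf in leaves]
    )
    zero_terminal = tip_depths - internal_depths <= 0
    if zero_terminal.any():
        warnings.warn(
            f"{int(zero_terminal.sum())} zero-length terminal branch(es) perturbed "
            "by 1e-8 x tree depth to keep C invertible",
            RuntimeWarning,
            stacklevel=2,
        )
        bump = 1e-8 * max_depth
        ii = np.where(zero_terminal)[0]
        C[ii, ii] += bump
    return C, labels


def _align_traits(
    traits: Mapping[str, float] | Sequence[float], labels: list[str]
) -> np.ndarray:
    if isinstance(traits, Mapping):
        missing = [lab for lab in labels if lab not in traits]
        if missing:
            raise InvalidParameterError(f"traits missing for tips: {missing}")
        return np.array([float(traits[lab]) for lab in labels])
    x = np.asarray(traits, dtype=float)
    if x.size != len(labels):
        raise InvalidParameterError(
            f"trait vector length {x.size} != number of tips {len(labels)}"
        )
    return x


def _k_from_vcv(C: np.ndarray, X: np.ndarray) -> np.ndarray:
    """K for each column of X given tip covariance C (vectorized)."""
    n = C.shape[0]
    ones = np.ones(n)
    try:
        Cinv_1 = np.linalg.solve(C, ones)
        Cinv_X = np.linalg.solve(C, X)
    except np.linalg.LinAlgError as exc:
        raise UndefinedStatisticError(f"singular tip covariance matrix: {exc}") from exc
    denom_gls = ones @ Cinv_1
    a_hat = (ones @ Cinv_X) / denom_gls
    R = X - a_hat  # residuals about the GLS mean, per column
    mse0 = np.einsum("ij,ij->j", R, R) / (n - 1)
    mse = np.einsum("ij,ij->j", R, Cinv_X - np.outer(Cinv_1, a_hat)) / (n - 1)
    expected = (np.trace(C) - n / denom_gls) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(
    tree: dendropy.Tree, traits: Mapping[str, float] | Sequence[float]
) -> float:
    """Blomberg's K for one trait on a rooted tree with branch lengths.

    ``traits`` is either a mapping from tip label to value or a sequence
    ordered as the tree's leaf nodes. Constant traits are rejected.
    """
    C, labels = vcv_from_tree(tree)
    x = _align_traits(traits, labels)
    if np.ptp(x) == 0.0:
        raise UndefinedStatisticError("K undefined for constant traits")
    return float(_k_from_vcv(C, x[:, None])[0])


def perm_test_k(
    tree: dendropy.Tree,
    traits: Mapping[str, float] | Sequence[float],
    n_perm: int = 999,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Tip-shuffle permutation test of Blomberg's K.

    The null distribution reassigns the observed trait values to tips
    uniformly at random; p = (1 + #{K_perm >= K_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise InvalidParameterError(f"n_perm must be >= 99, got {n_perm}")
    C, labels = vcv_from_tree(tree)
    x = _align_traits(traits, labels)
    if np.ptp(x) == 0.0:
        raise UndefinedStatisticError("K undefined for constant traits")
    k_obs = float(_k_from_vcv(C, x[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((x.size, n_perm))
    for j in range(n_perm):
        perms[:, j] = x[rng.permutation(x.size)]
    k_perm = _k_from_vcv(C, perms)
    p = (1 + int(np.count_nonzero(k_perm >= k_obs))) / (n_perm + 1)
    return PhyloSignalResult(k=k_obs, p_perm=float(p), n_perm=n_perm)
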