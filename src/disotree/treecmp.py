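"""Dendrogram comparison by leaf-pair path distances.

Two trees are compared by listing, for every unordered leaf pair, the
number of edges on the tree path between the two leaves, and taking the
Pearson correlation rho of the two vectors over the shared leaf pairs.
The combined dissimilarity is d' = 1 - m * rho, where m is the
leaf-set overlap fraction (Jaccard); for trees over the same leaf set
m = 1 and d' = 1 - rho.  Sets of trees are ordered for heat-map axes by
average-linkage clustering of the d' matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .distree import DistanceMatrix, cluster
from .errors import InsufficientOverlapError
from .tree import Dendrogram

__all__ = [
    "PathDistanceVector",
    "TreeSimilarity",
    "path_distances",
    "tree_correlation",
    "compare_tree_set",
]


@dataclass
class PathDistanceVector:
    """Edge-path distances for every unordered leaf pair of one tree."""

    pairs: dict[tuple[str, str], int]  # keys (a, b) with a < b

    @property
    def leaves(self) -> frozenset:
        out = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def restricted(self, leaves: frozenset) -> np.ndarray:
        keys = sorted(k for k in self.pairs if k[0] in leaves and k[1] in leaves)
        return np.array([self.pairs[k] for k in keys], dtype=float)


@dataclass
class TreeSimilarity:
    rho: float           # Pearson correlation of path-distance vectors
    m: float             # leaf-set overlap fraction (Jaccard)
    d_prime: float       # 1 - m * rho
    n_shared_leaves: int
    rho_defined: bool = True


def path_distances(tree: Dendrogram) -> PathDistanceVector:
    """Topological leaf-pair distances (edge counts; branch lengths ignored)."""
    if tree.n_leaves < 2:
        raise InsufficientOverlapError("tree has fewer than two leaves")
    return PathDistanceVector(tree.path_distances())


def tree_correlation(t1: Dendrogram, t2: Dendrogram) -> TreeSimilarity:
    """Correlate two dendrograms over their shared leaves.

    Pairs involving leaves absent from either tree are dropped before
    the correlation; the overlap fraction m penalises the mismatch in
    d' instead.  A zero-variance vector makes Pearson undefined; rho is
    then reported as 0 with a warning and an explicit flag.
    """
    leaves1, leaves2 = t1.leaf_set(), t2.leaf_set()
    shared = leaves1 & leaves2
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared leaves; need at least 3"
        )
    v1 = path_distances(t1).restricted(shared)
    v2 = path_distances(t2).restricted(shared)
    m = len(shared) / len(leaves1 | leaves2)
    rho_defined = v1.std() > 0 and v2.std() > 0
    if rho_defined:
        rho = float(np.corrcoef(v1, v2)[0, 1])
    else:
        warnings.warn(
            "path-distance vector has zero variance; reporting rho = 0",
            stacklevel=2,
        )
        rho = 0.0
    return TreeSimilarity(
        rho=rho,
        m=m,
        d_prime=1.0 - m * rho,
        n_shared_leaves=len(shared),
        rho_defined=rho_defined,
    )


def compare_tree_set(
    trees: list[tuple[str, Dendrogram]]
) -> tuple[np.ndarray, list[str]]:
    """Pairwise rho matrix over a named tree set, plus a heat-map ordering.

    The ordering comes from average-linkage clustering of the d'
    dissimilarity matrix (leaf order of the resulting dendrogram); for
    an all-tie matrix the deterministic tie rule returns input order.
    """
    if len(trees) < 2:
        raise InsufficientOverlapError("need at least two trees")
    names = [name for name, _ in trees]
    if len(set(names)) != len(names):
        raise ValueError("tree names must be unique")
    k = len(trees)
    rho = np.eye(k)
    dprime = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sim = tree_correlation(trees[i][1], trees[j][1])
            rho[i, j] = rho[j, i] = sim.rho
            dprime[i, j] = dprime[j, i] = sim.d_prime
    order_tree = cluster(DistanceMatrix(names, dprime), linkage="average")
    return rho, order_tree.leaf_names()
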