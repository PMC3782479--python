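"""Distance matrices and bootstrapped dendrograms from aligned disorder.

The tree-building route is: aligned disorder matrix -> Euclidean
distance between proteins (gap-aware) -> deterministic agglomerative
clustering -> per-edge support from multiscale bootstrap resampling of
alignment columns.

Support values follow the multiscale bootstrap scheme: at each scale r
the ``ceil(r * L)`` columns are resampled with replacement and the tree
recomputed; an edge's per-scale bootstrap proportion BP_r is the
fraction of replicate trees containing the same leaf bipartition.  BP is
BP_r at r = 1.  The approximately unbiased (AU) p-value comes from the
signed-distance/curvature fit

    psi_r = Phi^-1(1 - BP_r)  ~  v * sqrt(r) + c / sqrt(r)

by weighted least squares, with AU = 1 - Phi(v - c).  Standard errors
for BP and AU follow from the binomial counts by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .errors import DisotreeError, NoOverlapError
from .seqio import AlignedDisorderMatrix
from .tree import Dendrogram, Node

GAP_MODES = ("pairwise_complete", "gap_as_zero")
LINKAGES = ("average", "complete", "single")

DEFAULT_SCALES: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------
@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distance")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("nonzero diagonal")
        self.matrix = m


def disorder_distance(
    M: AlignedDisorderMatrix, gap_mode: str = "pairwise_complete"
) -> DistanceMatrix:
    """Pairwise Euclidean distances between protein disorder rows.

    ``pairwise_complete`` uses only columns where both proteins have a
    score and rescales to the full alignment length:
    ``d(i,j) = sqrt((L / |S_ij|) * sum_{c in S_ij} (x_ic - x_jc)^2)``,
    so sparser overlap does not shrink distances.  ``gap_as_zero``
    replaces missing cells by 0 and takes the plain Euclidean distance.
    """
    if gap_mode not in GAP_MODES:
        raise ValueError(f"gap_mode must be one of {GAP_MODES}")
    if M.n_proteins < 2:
        raise DisotreeError("need at least two proteins")
    X = M.values
    L = X.shape[1]
    V = np.isfinite(X)
    B = np.where(V, X, 0.0)
    # direct squared differences (no Gram-matrix cancellation, so identical
    # rows come out at exactly zero); n is small enough to broadcast
    diff2 = (B[:, None, :] - B[None, :, :]) ** 2
    if gap_mode == "gap_as_zero":
        d = np.sqrt(diff2.sum(axis=2))
    else:
        both = V[:, None, :] & V[None, :, :]
        counts = both.sum(axis=2)
        off_diag = ~np.eye(len(M.ids), dtype=bool)
        if np.any(counts[off_diag] == 0):
            i, j = np.argwhere((counts == 0) & off_diag)[0]
            raise NoOverlapError(
                f"proteins {M.ids[i]!r} and {M.ids[j]!r} share no scored column"
            )
        sumsq = np.where(both, diff2, 0.0).sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.sqrt(np.where(counts > 0, L / counts, 0.0) * sumsq)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, d.T)  # exact symmetry (kernel is symmetric up to rounding)
    return DistanceMatrix(list(M.ids), d)


# ----------------------------------------------------------------------
# deterministic agglomerative clustering
# ----------------------------------------------------------------------
def _agglomerate(
    D: np.ndarray, linkage: str
) -> list[tuple[int, int, float]]:
    """Agglomerative merge schedule with a deterministic tie rule.

    Returns merges as (slot_i, slot_j, height) over cluster slots
    0..2n-2; leaves occupy slots 0..n-1 in input order and each merge
    creates the next slot.  Equal-distance ties are broken by merging
    the pair whose member clusters contain the earliest input indices
    (smaller representative first), which makes the all-ties degenerate
    case a left-to-right caterpillar.
    """
    n = D.shape[0]
    active: dict[int, int] = {i: i for i in range(n)}  # slot -> representative
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_slot = n
    while len(active) > 1:
        best = None
        for (i, j), dij in dist.items():
            key = (dij, min(active[i], active[j]), max(active[i], active[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        height = dist[(i, j)]
        ni, nj = sizes[i], sizes[j]
        # Lance-Williams update for the new cluster
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            if linkage == "average":
                dnew = (ni * dik + nj * djk) / (ni + nj)
            elif linkage == "complete":
                dnew = max(dik, djk)
            else:
                dnew = min(dik, djk)
            dist[(k, next_slot)] = dnew
        for k in list(dist):
            if i in k or j in k:
                del dist[k]
        rep = min(active[i], active[j])
        merges.append((i, j, height))
        del active[i], active[j]
        active[next_slot] = rep
        sizes[next_slot] = ni + nj
        next_slot += 1
    return merges


def cluster(D: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Deterministic hierarchical clustering of a distance matrix.

    Heights are cophenetic merge distances (non-decreasing toward the
    root under average linkage).  Ties merge the earliest input ids
    first, so the result is reproducible regardless of float ordering
    accidents.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = len(D.ids)
    if n == 1:
        return Dendrogram(Node(name=D.ids[0], height=0.0))
    merges = _agglomerate(D.matrix, linkage)
    nodes: dict[int, Node] = {
        i: Node(name=D.ids[i], height=0.0) for i in range(n)
    }
    reps: dict[int, int] = {i: i for i in range(n)}
    slot = n
    for i, j, height in merges:
        # earlier-input cluster becomes the left child
        if reps[i] > reps[j]:
            i, j = j, i
        nodes[slot] = Node(height=height, children=[nodes[i], nodes[j]])
        reps[slot] = min(reps[i], reps[j])
        slot += 1
    return Dendrogram(nodes[slot - 1])


def _merge_bipartitions(
    merges: list[tuple[int, int, float]], ids: Sequence[str]
) -> set[frozenset]:
    """Proper clades (>= 2 leaves, not all) implied by a merge schedule."""
    n = len(ids)
    members: dict[int, frozenset] = {i: frozenset([ids[i]]) for i in range(n)}
    out = set()
    slot = n
    for i, j, _ in merges:
        s = members[i] | members[j]
        members[slot] = s
        slot += 1
        if 1 < len(s) < n:
            out.add(s)
    return out


# ----------------------------------------------------------------------
# multiscale bootstrap
# ----------------------------------------------------------------------
@dataclass
class BootstrapSupport:
    """Support record for one internal edge (leaf bipartition)."""

    edge_id: int
    clade: frozenset
    bp: float  # percent in [0, 100]
    au: float  # percent in [0, 100]
    se_bp: float
    se_au: float
    counts: dict = field(default_factory=dict)  # scale r -> (hits, replicates)
    v: float = float("nan")
    c: float = float("nan")
    degenerate: bool = False


def _fit_au(counts: dict) -> tuple[float, float, float, float, bool]:
    """Fit psi_r = v sqrt(r) + c / sqrt(r); return (au, se_au, v, c, degenerate).

    Scales where the edge appeared in no or all replicates carry no
    information about the curve and are dropped from the fit; if fewer
    than two informative scales remain the AU value is pinned to the
    unanimous BP (0 or 100) and flagged degenerate.
    """
    usable = {r: (h, m) for r, (h, m) in counts.items() if 0 < h < m}
    if len(usable) < 2:
        hits = sum(h for h, _ in counts.values())
        total = sum(m for _, m in counts.values())
        au = 100.0 if hits >= total / 2 else 0.0
        return au, float("nan"), float("nan"), float("nan"), True
    rs = np.array(sorted(usable))
    bp = np.array([usable[r][0] / usable[r][1] for r in rs])
    m = np.array([usable[r][1] for r in rs], dtype=float)
    psi = norm.ppf(1.0 - bp)
    # inverse-variance weights from binomial counts by the delta method
    w = m * norm.pdf(psi) ** 2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(rs), 1.0 / np.sqrt(rs)])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    v, c = cov @ (XtW @ psi)
    au = float(1.0 - norm.cdf(v - c))
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    se_au = float(norm.pdf(v - c) * np.sqrt(max(var_diff, 0.0)) * 100.0)
    return au * 100.0, se_au, float(v), float(c), False


def bootstrap_tree(
    M: AlignedDisorderMatrix,
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
    gap_mode: str = "pairwise_complete",
    linkage: str = "average",
) -> tuple[Dendrogram, list[BootstrapSupport]]:
    """Build the dendrogram and attach BP/AU support to every edge.

    ``n_boot`` replicates are drawn at each scale r in ``scales`` (1.0
    must be included, since BP is defined there); each replicate
    resamples ``ceil(r * L)`` alignment columns with replacement and
    rebuilds the tree.  Per-scale random streams are derived from the
    single ``seed``, so results are reproducible and independent of
    protein input order.
    """
    scales = [round(float(r), 10) for r in scales]
    if 1.0 not in scales:
        raise ValueError("scales must include 1.0 (BP is defined at scale 1)")
    if n_boot < 100:
        raise ValueError("need at least 100 replicates per scale")

    base_tree, merges = _tree_and_merges(M, gap_mode, linkage)
    edges = sorted(_merge_bipartitions(merges, M.ids), key=lambda s: (len(s), sorted(s)))
    hits = {r: {e: 0 for e in edges} for r in scales}

    X = M.values
    L = X.shape[1]
    root_ss = np.random.SeedSequence(seed)
    streams = {
        r: np.random.default_rng(child)
        for r, child in zip(scales, root_ss.spawn(len(scales)))
    }
    for r in scales:
        rng = streams[r]
        m_cols = int(np.ceil(r * L))
        for _ in range(n_boot):
            cols = rng.integers(0, L, size=m_cols)
            sub = AlignedDisorderMatrix(M.ids, X[:, cols])
            try:
                D = disorder_distance(sub, gap_mode)
            except NoOverlapError:
                continue  # replicate uninformative for all edges
            rep_bips = _merge_bipartitions(
                _agglomerate(D.matrix, linkage), M.ids
            )
            for e in edges:
                if e in rep_bips:
                    hits[r][e] += 1

    supports = []
    clade_to_support = {}
    for k, e in enumerate(edges):
        counts = {r: (hits[r][e], n_boot) for r in scales}
        bp = counts[1.0][0] / counts[1.0][1]
        se_bp = float(np.sqrt(bp * (1 - bp) / n_boot) * 100.0)
        au, se_au, v, c, degenerate = _fit_au(counts)
        sup = BootstrapSupport(
            edge_id=k,
            clade=e,
            bp=bp * 100.0,
            au=au,
            se_bp=se_bp,
            se_au=se_au,
            counts=counts,
            v=v,
            c=c,
            degenerate=degenerate,
        )
        supports.append(sup)
        clade_to_support[e] = sup

    _attach_supports(base_tree, clade_to_support)
    return base_tree, supports


def _tree_and_merges(M, gap_mode, linkage):
    D = disorder_distance(M, gap_mode)
    merges = _agglomerate(D.matrix, linkage)
    tree = cluster(D, linkage)
    return tree, merges


def _attach_supports(tree: Dendrogram, clade_to_support: dict) -> None:
    def visit(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        members = frozenset().union(*(visit(c) for c in node.children))
        sup = clade_to_support.get(members)
        if sup is not None:
            node.support = sup
            node.edge_id = sup.edge_id
        return members

    visit(tree.root)


def export_tree(
    tree: Dendrogram,
    supports: Optional[list[BootstrapSupport]] = None,
    path: Union[str, Path, None] = None,
) -> str:
    """Serialise the supported tree to Newick with ``au|bp`` internal labels.

    Labels are integer percents.  When ``path`` is given the Newick is
    also written there; the string is returned either way.
    """
    for node in tree.internal_nodes():
        if node.support is not None:
            node.name = f"{round(node.support.au)}|{round(node.support.bp)}"
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
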