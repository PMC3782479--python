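"""Synthetic protein families with clade-structured disorder profiles.

The generator emulates the situation the pipeline is built for: a family
of proteins whose per-residue disorder profiles are conserved within
clades and divergent between clades, observed through a gapped multiple
alignment, with short linear-motif annotations that may or may not
prefer disordered regions.  Every pipeline stage can therefore be
exercised, and statistically calibrated, without any external data.

Model: each clade has a piecewise-linear archetype profile over the
alignment columns; clade archetypes are separated by a target mean
absolute difference ``delta``.  A protein is its clade archetype plus
i.i.d. Gaussian noise of sd ``sigma``, truncated to [0, 1].  Gaps are
contiguous runs (geometric length, mean 3 columns — indel-like) placed
to hit an expected per-cell gap rate.  Motifs are planted with start
positions weighted by ``omega`` when the local mean disorder exceeds
0.5, so ``omega = 1`` is the uniform null and larger values plant
motifs preferentially in disordered regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import DisotreeError
from .seqio import Alignment, DisorderProfile, MotifAnnotation
from .tree import Dendrogram, Node

# residues loosely grouped by disorder propensity; used only to make the
# synthetic sequences qualitatively sensible for sequence-side tools
_DISORDER_POOL = list("PESKQRGA")
_ORDER_POOL = list("WFYILVMCTNHD")

_MOTIF_CATEGORIES = ("CLV", "LIG", "MOD", "TRG")
_GAP_RUN_MEAN = 3.0


@dataclass(frozen=True)
class FamilyConfig:
    """Generation parameters for one synthetic family."""

    n_clades: int = 3
    proteins_per_clade: int = 4
    length: int = 300            # alignment columns
    segments: int = 8            # piecewise-linear archetype segments
    sigma: float = 0.04          # within-clade per-residue noise sd
    delta: float = 0.4           # mean |archetype difference| between clades
    gap_rate: float = 0.02       # expected fraction of gap cells per row
    motif_enrichment_odds: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.gap_rate < 0.5):
            raise ValueError("gap_rate must lie in [0, 0.5)")
        if self.motif_enrichment_odds < 1:
            raise ValueError("motif_enrichment_odds must be >= 1")
        if not (0 < self.delta <= 1):
            raise ValueError("delta must lie in (0, 1]")
        if self.n_clades < 1 or self.proteins_per_clade < 1:
            raise ValueError("need at least one clade and one protein per clade")


@dataclass
class SyntheticFamily:
    alignment: Alignment
    profiles: list[DisorderProfile]
    truth_tree: Dendrogram
    true_clades: list[frozenset]
    motifs: list[MotifAnnotation] = field(default_factory=list)
    config: Optional[FamilyConfig] = None


def _piecewise(rng: np.random.Generator, length: int, segments: int,
               lo: float, hi: float) -> np.ndarray:
    knots_x = np.linspace(0, length - 1, segments + 1)
    knots_y = rng.uniform(lo, hi, size=segments + 1)
    return np.interp(np.arange(length), knots_x, knots_y)


def _clade_archetypes(rng: np.random.Generator, cfg: FamilyConfig) -> np.ndarray:
    base = _piecewise(rng, cfg.length, cfg.segments, 0.3, 0.7)
    if cfg.n_clades == 1:
        return base[None, :]
    offsets = np.stack(
        [
            np.interp(
                np.arange(cfg.length),
                np.linspace(0, cfg.length - 1, cfg.segments + 1),
                rng.standard_normal(cfg.segments + 1),
            )
            for _ in range(cfg.n_clades)
        ]
    )
    offsets -= offsets.mean(axis=0, keepdims=True)
    pair_diffs = [
        np.mean(np.abs(offsets[i] - offsets[j]))
        for i in range(cfg.n_clades)
        for j in range(i + 1, cfg.n_clades)
    ]
    mean_sep = float(np.mean(pair_diffs))
    if mean_sep > 0:
        offsets *= cfg.delta / mean_sep
    return np.clip(base[None, :] + offsets, 0.02, 0.98)


def _gap_mask(rng: np.random.Generator, length: int, gap_rate: float) -> np.ndarray:
    """Indel-like gap runs: geometric lengths (mean 3), expected cell rate."""
    mask = np.zeros(length, dtype=bool)
    if gap_rate <= 0:
        return mask
    n_runs = rng.poisson(gap_rate * length / _GAP_RUN_MEAN)
    for _ in range(n_runs):
        run = rng.geometric(1.0 / _GAP_RUN_MEAN)
        start = rng.integers(0, length)
        mask[start : start + run] = True
    if mask.all():  # keep at least one residue per row
        mask[rng.integers(0, length)] = False
    return mask


def _truth_tree(clade_ids: list[list[str]]) -> tuple[Dendrogram, list[frozenset]]:
    """Caterpillar-of-caterpillars ground truth with labelled clade roots."""

    def caterpillar(names: Sequence[str], base_height: float) -> Node:
        node = Node(name=names[0], height=0.0)
        for k, name in enumerate(names[1:], start=1):
            node = Node(
                height=base_height * k / len(names),
                children=[node, Node(name=name, height=0.0)],
            )
        return node

    clade_roots = []
    for k, names in enumerate(clade_ids):
        root = caterpillar(names, base_height=0.5)
        if not root.is_leaf:
            root.name = f"clade{k + 1}"
        clade_roots.append(root)
    tree_root = clade_roots[0]
    for k, clade_root in enumerate(clade_roots[1:], start=1):
        tree_root = Node(height=1.0 + 0.5 * k, children=[tree_root, clade_root])
    clades = [frozenset(names) for names in clade_ids]
    return Dendrogram(tree_root), clades


def generate_family(cfg: FamilyConfig) -> SyntheticFamily:
    """Deterministically generate a family from its config (same seed, same family)."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_clades > 1 and cfg.delta == 0 and cfg.sigma == 0:
        raise DisotreeError("delta = sigma = 0 makes all proteins identical")
    archetypes = _clade_archetypes(rng, cfg)

    clade_ids: list[list[str]] = []
    rows: list[tuple[str, str]] = []
    profiles: list[DisorderProfile] = []
    for k in range(cfg.n_clades):
        names = [f"C{k + 1}P{p + 1}" for p in range(cfg.proteins_per_clade)]
        clade_ids.append(names)
        for name in names:
            scores = np.clip(
                archetypes[k] + rng.normal(0.0, cfg.sigma, size=cfg.length),
                0.0,
                1.0,
            )
            gaps = _gap_mask(rng, cfg.length, cfg.gap_rate)
            residue_scores = scores[~gaps]
            pick_disordered = rng.random(residue_scores.size) < residue_scores
            letters = np.where(
                pick_disordered,
                rng.choice(_DISORDER_POOL, size=residue_scores.size),
                rng.choice(_ORDER_POOL, size=residue_scores.size),
            )
            row = np.full(cfg.length, "-", dtype="<U1")
            row[~gaps] = letters
            rows.append((name, "".join(row)))
            profiles.append(DisorderProfile(name, residue_scores))

    truth_tree, true_clades = _truth_tree(clade_ids)
    return SyntheticFamily(
        alignment=Alignment(rows),
        profiles=profiles,
        truth_tree=truth_tree,
        true_clades=true_clades,
        motifs=[],
        config=cfg,
    )


def plant_motifs(
    fam: SyntheticFamily,
    n_motifs: int = 36,
    motif_length: int = 8,
    omega: Optional[float] = None,
    seed: int = 0,
) -> SyntheticFamily:
    """Plant short motif annotations, optionally biased toward disorder.

    A start position's sampling weight is ``omega`` when the mean
    disorder over the motif window exceeds 0.5 and 1 otherwise, so
    ``omega = 1`` is the uniform null.  Categories rotate over
    CLV/LIG/MOD/TRG.  Returns a copy of the family with motifs attached.
    """
    if omega is None:
        omega = fam.config.motif_enrichment_odds if fam.config else 1.0
    if omega < 1:
        raise ValueError("omega must be >= 1")
    rng = np.random.default_rng(seed)

    candidates: list[tuple[str, int]] = []
    weights: list[float] = []
    for prof in fam.profiles:
        n = len(prof)
        if n < motif_length:
            continue
        csum = np.concatenate([[0.0], np.cumsum(prof.scores)])
        window_means = (csum[motif_length:] - csum[:-motif_length]) / motif_length
        for start0, mean in enumerate(window_means):
            candidates.append((prof.id, start0 + 1))
            weights.append(omega if mean > 0.5 else 1.0)
    if not candidates:
        raise DisotreeError(
            f"no protein can host a motif of length {motif_length}"
        )
    w = np.array(weights)
    idx = rng.choice(len(candidates), size=n_motifs, replace=True, p=w / w.sum())
    motifs = []
    for i, pick in enumerate(idx):
        pid, start = candidates[pick]
        category = _MOTIF_CATEGORIES[i % len(_MOTIF_CATEGORIES)]
        motifs.append(
            MotifAnnotation(
                protein_id=pid,
                motif_id=f"SYN_{category}_{i + 1}",
                category=category,
                start=start,
                end=start + motif_length - 1,
            )
        )
    return replace(fam, motifs=list(fam.motifs) + motifs)


def clade_recovery(
    inferred: Dendrogram,
    truth: Dendrogram,
    clades: Optional[Sequence[frozenset]] = None,
) -> float:
    """Fraction of true clades present as leaf bipartitions of ``inferred``.

    By default every non-trivial bipartition of ``truth`` is checked;
    pass ``clades`` (e.g. a family's planted clade leaf sets) to score
    only the splits that are meaningful ground truth.
    """
    if inferred.leaf_set() != truth.leaf_set():
        raise DisotreeError("trees have different leaf sets")
    full = truth.leaf_set()
    if clades is None:
        targets = set(truth.bipartitions())
    else:
        targets = set()
        for clade in clades:
            side = frozenset(clade)
            if not side <= full:
                raise DisotreeError(f"clade {sorted(side)} not a subset of leaves")
            if 1 < len(side) < len(full):
                targets.add(side)
    if not targets:
        return 1.0
    inferred_bips = inferred.bipartitions()
    return sum(1 for t in targets if t in inferred_bips) / len(targets)
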