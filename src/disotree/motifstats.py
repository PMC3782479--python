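"""Linear-motif / disorder statistics.

Covers the enrichment questions asked of ELM (eukaryotic linear motif)
and ANCHOR (predicted disorder-embedded binding region) annotations:

* are disorder scores higher at positions covered by ELMs than
  elsewhere (one-sided Mann-Whitney / Wilcoxon rank-sum, pooled over
  proteins, positions never double-counted across overlapping motifs)?
* per motif id, are its covered positions more disordered than the
  protein's full score set (a deliberately conservative comparison: the
  covered scores stay inside the reference set)?
* which ELMs overlap ANCHOR regions, counted per category
  (CLV/LIG/MOD/TRG), with a chi-squared goodness-of-fit of the
  ANCHOR-associated category mix against the overall mix and per
  category two-tailed Fisher exact tests?
* per-protein ANCHOR coverage summaries (region count, residues,
  percent of length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    InconsistentCountsError,
    UnknownIdError,
)
from .seqio import DisorderProfile, MotifAnnotation

ELM_CATEGORIES = ("CLV", "LIG", "MOD", "TRG")

# exact Mann-Whitney above this problem size is needlessly slow; the
# normal approximation with tie correction is accurate there.
# _ENUM_LIMIT bounds the number of label splits enumerated by the exact
# (tie-aware) permutation path.
_ENUM_LIMIT = 200_000
_EXACT_LIMIT = 50


@dataclass
class EnrichmentResult:
    statistic: float
    p_value: float
    test: str
    sidedness: str
    n1: int
    n2: int


@dataclass
class CategoryCounts:
    """Per-category ELM totals and ANCHOR-associated subtotals."""

    totals: dict[str, int]      # category -> total ELM count n_c
    associated: dict[str, int]  # category -> ANCHOR-associated count a_c

    def __post_init__(self):
        for c in ELM_CATEGORIES:
            self.totals.setdefault(c, 0)
            self.associated.setdefault(c, 0)
        for c, a in self.associated.items():
            n = self.totals.get(c, 0)
            if not (0 <= a <= n):
                raise InconsistentCountsError(
                    f"category {c}: associated {a} outside [0, total {n}]"
                )

    @property
    def N(self) -> int:
        return sum(self.totals[c] for c in ELM_CATEGORIES)

    @property
    def A(self) -> int:
        return sum(self.associated[c] for c in ELM_CATEGORIES)


# ----------------------------------------------------------------------
# rank tests on disorder scores
# ----------------------------------------------------------------------
def _profiles_by_id(
    profiles: Iterable[DisorderProfile] | Mapping[str, DisorderProfile]
) -> dict[str, DisorderProfile]:
    if isinstance(profiles, Mapping):
        return dict(profiles)
    return {p.id: p for p in profiles}


def _covered_masks(
    profiles: dict[str, DisorderProfile], motifs: Sequence[MotifAnnotation]
) -> dict[str, np.ndarray]:
    masks = {pid: np.zeros(len(p), dtype=bool) for pid, p in profiles.items()}
    for m in motifs:
        if m.protein_id not in profiles:
            raise UnknownIdError(f"no profile for {m.protein_id!r} ({m.motif_id})")
        if m.end > len(profiles[m.protein_id]):
            raise UnknownIdError(
                f"{m.motif_id} on {m.protein_id}: end {m.end} beyond profile"
            )
        masks[m.protein_id][m.start - 1 : m.end] = True
    return masks


def _mannwhitney_greater(x: np.ndarray, y: np.ndarray, test_name: str) -> EnrichmentResult:
    """One-sided Mann-Whitney, exact whenever exact is affordable.

    Small problems get a full tie-aware permutation enumeration; medium
    tie-free problems use the classical exact distribution; everything
    else falls back to the normal approximation with tie correction.
    """
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError(f"{test_name}: empty group")
    from math import comb

    n_splits = comb(x.size + y.size, min(x.size, y.size))
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if min(x.size, y.size) == 1:
        return _singleton_exact_greater(x, y, test_name)
    if n_splits <= _ENUM_LIMIT:
        method = stats.PermutationMethod(n_resamples=_ENUM_LIMIT + 1)
        method_name = "exact"
    elif not has_ties and max(x.size, y.size) <= _EXACT_LIMIT:
        method = "exact"
        method_name = "exact"
    else:
        method = "asymptotic"
        method_name = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return EnrichmentResult(
        statistic=float(res.statistic),
        p_value=float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0)),
        test=f"mann-whitney-{method_name}",
        sidedness="greater",
        n1=int(x.size),
        n2=int(y.size),
    )


def _singleton_exact_greater(
    x: np.ndarray, y: np.ndarray, test_name: str
) -> EnrichmentResult:
    """Exact one-sided p when one group is a single observation.

    The permutation null makes every pooled value equally likely to be
    the singleton; the p-value is the fraction of placements with a U
    statistic at least the observed one (midrank convention for ties).
    """
    pooled = np.concatenate([x, y])

    def u_first(v: float, rest: np.ndarray) -> float:
        return float(np.sum(v > rest) + 0.5 * np.sum(v == rest))

    if x.size == 1:
        obs = u_first(x[0], y)
        us = [
            u_first(pooled[i], np.delete(pooled, i)) for i in range(pooled.size)
        ]
    else:  # y is the singleton; U counts x-values above it
        obs = float(np.sum(x > y[0]) + 0.5 * np.sum(x == y[0]))
        us = [
            float(
                np.sum(np.delete(pooled, i) > pooled[i])
                + 0.5 * np.sum(np.delete(pooled, i) == pooled[i])
            )
            for i in range(pooled.size)
        ]
    p = float(np.mean([u >= obs - 1e-12 for u in us]))
    return EnrichmentResult(
        statistic=obs,
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        test="mann-whitney-exact",
        sidedness="greater",
        n1=int(x.size),
        n2=int(y.size),
    )


def elm_idr_global_test(
    profiles: Iterable[DisorderProfile] | Mapping[str, DisorderProfile],
    elms: Sequence[MotifAnnotation],
) -> EnrichmentResult:
    """Pooled one-sided test that ELM-covered positions are more disordered.

    The covered set is the union of all ELM intervals (a position under
    several overlapping motifs counts once); the reference set is every
    other scored position across all proteins.
    """
    prof = _profiles_by_id(profiles)
    masks = _covered_masks(prof, elms)
    covered = np.concatenate([prof[pid].scores[m] for pid, m in masks.items()])
    uncovered = np.concatenate([prof[pid].scores[~m] for pid, m in masks.items()])
    if covered.size == 0:
        raise DegenerateInputError("no position is covered by any ELM")
    if uncovered.size == 0:
        raise DegenerateInputError("every position is covered; no reference set")
    return _mannwhitney_greater(covered, uncovered, "global ELM/IDR test")


def elm_idr_per_motif_test(
    profiles: Iterable[DisorderProfile] | Mapping[str, DisorderProfile],
    elms: Sequence[MotifAnnotation],
    motif_id: str,
) -> EnrichmentResult:
    """One-sided test for a single motif id against the full score set.

    The reference set includes the covered positions themselves, which
    slightly understates any enrichment but keeps the reference set
    identical across motifs.
    """
    prof = _profiles_by_id(profiles)
    selected = [m for m in elms if m.motif_id == motif_id]
    if not selected:
        raise UnknownIdError(f"motif {motif_id!r} not present in annotations")
    masks = _covered_masks(prof, selected)
    covered = np.concatenate([prof[pid].scores[m] for pid, m in masks.items()])
    everything = np.concatenate([p.scores for p in prof.values()])
    return _mannwhitney_greater(covered, everything, f"per-motif test ({motif_id})")


# ----------------------------------------------------------------------
# ELM x ANCHOR association
# ----------------------------------------------------------------------
def _overlaps(a: MotifAnnotation, b: MotifAnnotation) -> bool:
    return a.protein_id == b.protein_id and a.start <= b.end and b.start <= a.end


def anchor_association(
    elms: Sequence[MotifAnnotation], anchors: Sequence[MotifAnnotation]
) -> CategoryCounts:
    """Count ELMs per category, splitting out those overlapping ANCHOR regions.

    An ELM is ANCHOR-associated iff it shares at least one residue with
    at least one ANCHOR region on the same protein.
    """
    totals = {c: 0 for c in ELM_CATEGORIES}
    associated = {c: 0 for c in ELM_CATEGORIES}
    for elm in elms:
        if elm.category not in ELM_CATEGORIES:
            raise InconsistentCountsError(
                f"{elm.motif_id}: category {elm.category!r} is not an ELM category"
            )
        totals[elm.category] += 1
        if any(_overlaps(elm, a) for a in anchors):
            associated[elm.category] += 1
    return CategoryCounts(totals=totals, associated=associated)


def category_chisq(counts: CategoryCounts) -> EnrichmentResult:
    """Goodness-of-fit of the ANCHOR-associated category mix.

    Observed (a_CLV, a_LIG, a_MOD, a_TRG) against expected
    A * n_c / N — i.e. are ANCHOR-associated ELMs distributed over
    categories like ELMs overall?  Two-tailed chi-squared with df = 3,
    no continuity correction.
    """
    if counts.A < 1:
        raise DegenerateInputError("no ANCHOR-associated ELM; test undefined")
    obs = np.array([counts.associated[c] for c in ELM_CATEGORIES], dtype=float)
    exp = counts.A * np.array(
        [counts.totals[c] / counts.N for c in ELM_CATEGORIES]
    )
    keep = exp > 0
    stat = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
    p = float(stats.chi2.sf(stat, df=3))
    return EnrichmentResult(
        statistic=stat,
        p_value=max(p, np.nextafter(0, 1)),
        test="chi-squared-gof",
        sidedness="two-tailed",
        n1=counts.A,
        n2=counts.N,
    )


def category_fisher(counts: CategoryCounts, category: str) -> EnrichmentResult:
    """Two-tailed Fisher exact test for one category's ANCHOR association.

    The 2x2 table is {in category, other categories} x
    {ANCHOR-associated, not associated}; the two-tailed p sums the
    hypergeometric point probabilities not exceeding the observed
    table's.
    """
    if category not in ELM_CATEGORIES:
        raise ValueError(f"category must be one of {ELM_CATEGORIES}")
    a = counts.associated[category]
    b = counts.totals[category] - a
    c = counts.A - a
    d = (counts.N - counts.totals[category]) - c
    if counts.N < 1:
        raise DegenerateInputError("empty count table")
    if min(a + b, c + d) < 0 or d < 0:
        raise InconsistentCountsError("negative cell in 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentResult(
        statistic=float(odds),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        test="fisher-exact",
        sidedness="two-tailed",
        n1=a + b,
        n2=c + d,
    )


# ----------------------------------------------------------------------
# ANCHOR coverage
# ----------------------------------------------------------------------
def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def anchor_summary(
    anchors: Sequence[MotifAnnotation], seq_length: int
) -> tuple[int, int, int]:
    """(region count, residues covered, integer percent of sequence length).

    Overlapping regions are merged before residues are counted, so a
    residue inside two regions counts once.  The region count is the
    number of input regions, as annotation tables report them.
    """
    for a in anchors:
        if a.end > seq_length:
            raise UnknownIdError(
                f"{a.motif_id} on {a.protein_id}: end {a.end} beyond "
                f"sequence length {seq_length}"
            )
    merged = merge_intervals([(a.start, a.end) for a in anchors])
    residues = sum(e - s + 1 for s, e in merged)
    percent = int(round(100.0 * residues / seq_length))
    return len(anchors), residues, percent
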