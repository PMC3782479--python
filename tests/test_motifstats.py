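from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.stats import hypergeom

from disotree.errors import (
    DegenerateInputError,
    InconsistentCountsError,
    UnknownIdError,
)
from disotree.motifstats import (
    ELM_CATEGORIES,
    CategoryCounts,
    anchor_association,
    anchor_summary,
    category_chisq,
    category_fisher,
    elm_idr_global_test,
    elm_idr_per_motif_test,
    merge_intervals,
)
from disotree.seqio import DisorderProfile, MotifAnnotation


def _motif(pid, start, end, motif_id="M1", category="LIG"):
    return MotifAnnotation(pid, motif_id, category, start, end)


def _exact_mw_greater_p(x, y):
    """Exact permutation oracle: P(U >= observed) over all label splits."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {}

    def u_stat(group):
        u = 0
        rest = list(pooled)
        g = list(group)
        for gi in g:
            rest.remove(gi)
        for a in g:
            for b in rest:
                u += (a > b) + 0.5 * (a == b)
        return u

    observed = u_stat(x)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        group = [pooled[i] for i in idx]
        total += 1
        if u_stat(group) >= observed - 1e-12:
            count += 1
    return count / total


# ----------------------------------------------------------------------
# global rank test
# ----------------------------------------------------------------------
def test_global_test_extreme_separation_exact_p():
    """All covered scores above all uncovered ones: the one-sided exact p is
    the probability of the single most extreme labelling, 1/C(20,10)."""
    prof = DisorderProfile("P", np.array([0.9] * 10 + [0.1] * 10))
    elms = [_motif("P", 1, 10)]
    res = elm_idr_global_test([prof], elms)
    assert res.p_value == pytest.approx(1 / comb(20, 10))
    assert res.n1 == 10 and res.n2 == 10


def test_global_test_null_symmetry():
    scores = np.linspace(0.05, 0.95, 10)
    prof = DisorderProfile("P", np.concatenate([scores, scores]))
    res = elm_idr_global_test([prof], [_motif("P", 1, 10)])
    assert res.p_value == pytest.approx(0.5, abs=0.05)


def test_global_test_does_not_double_count_overlaps():
    prof = DisorderProfile("P", np.linspace(0, 1, 20))
    overlapping = [_motif("P", 3, 8, "A"), _motif("P", 5, 10, "B")]
    merged = [_motif("P", 3, 10, "C")]
    r1 = elm_idr_global_test([prof], overlapping)
    r2 = elm_idr_global_test([prof], merged)
    assert r1.statistic == r2.statistic
    assert r1.p_value == r2.p_value
    assert r1.n1 == 8


def test_global_test_matches_exact_permutation_oracle(rng):
    scores = rng.permutation(np.round(np.linspace(0.02, 0.98, 12), 3))
    prof = DisorderProfile("P", scores)
    res = elm_idr_global_test([prof], [_motif("P", 4, 7)])
    covered = scores[3:7]
    uncovered = np.concatenate([scores[:3], scores[7:]])
    assert res.p_value == pytest.approx(_exact_mw_greater_p(covered, uncovered))


def test_global_test_invariant_to_relabeling_and_motif_order(rng):
    s1, s2 = rng.random(15), rng.random(12)
    motifs = [_motif("A", 2, 6, "M1"), _motif("B", 1, 4, "M2")]
    p1 = elm_idr_global_test(
        [DisorderProfile("A", s1), DisorderProfile("B", s2)], motifs
    ).p_value
    renamed = [_motif("Y", 2, 6, "M1"), _motif("Z", 1, 4, "M2")]
    p2 = elm_idr_global_test(
        [DisorderProfile("Z", s2), DisorderProfile("Y", s1)], renamed[::-1]
    ).p_value
    assert p1 == p2


def test_global_test_degenerate_inputs():
    prof = DisorderProfile("P", np.linspace(0, 1, 8))
    with pytest.raises(DegenerateInputError):
        elm_idr_global_test([prof], [_motif("P", 1, 8)])  # no complement
    with pytest.raises(DegenerateInputError):
        elm_idr_global_test([prof], [])  # nothing covered
    with pytest.raises(UnknownIdError):
        elm_idr_global_test([prof], [_motif("Q", 1, 3)])


# ----------------------------------------------------------------------
# per-motif test
# ----------------------------------------------------------------------
def test_per_motif_covering_maximum_positions_is_significant():
    scores = np.array(
        [0.95, 0.9, 0.92, 0.2, 0.1, 0.15, 0.25, 0.3, 0.05, 0.12, 0.22, 0.18]
    )
    prof = DisorderProfile("P", scores)
    res = elm_idr_per_motif_test([prof], [_motif("P", 1, 3, "TOP")], "TOP")
    oracle = _exact_mw_greater_p(scores[:3], scores)
    assert res.p_value == pytest.approx(oracle)
    assert res.p_value < 0.05


def test_per_motif_covering_everything_is_null():
    prof = DisorderProfile("P", np.linspace(0.1, 0.9, 12))
    res = elm_idr_per_motif_test([prof], [_motif("P", 1, 12, "ALL")], "ALL")
    assert res.p_value == pytest.approx(0.5, abs=0.1)


def test_per_motif_is_conservative_vs_strict_complement(rng):
    """Keeping the covered scores inside the reference set attenuates the
    evidence, so in the enrichment regime the inclusive p-value can only
    understate significance relative to the strict complement."""
    from disotree.motifstats import _mannwhitney_greater

    checked = 0
    for _ in range(40):
        scores = rng.random(18)
        prof = DisorderProfile("P", scores)
        start = int(rng.integers(1, 14))
        end = start + int(rng.integers(0, 4))
        res = elm_idr_per_motif_test(
            [prof], [_motif("P", start, end, "M")], "M"
        )
        strict = _mannwhitney_greater(
            scores[start - 1 : end],
            np.concatenate([scores[: start - 1], scores[end:]]),
            "strict",
        )
        if strict.p_value < 0.4:  # evidence of enrichment
            assert res.p_value >= strict.p_value - 1e-12
            checked += 1
    assert checked >= 5


def test_per_motif_absent_motif_raises():
    prof = DisorderProfile("P", np.linspace(0, 1, 5))
    with pytest.raises(UnknownIdError):
        elm_idr_per_motif_test([prof], [_motif("P", 1, 2, "M")], "OTHER")


# ----------------------------------------------------------------------
# ANCHOR association counting
# ----------------------------------------------------------------------
def test_one_residue_overlap_counts_as_associated():
    elm = [_motif("P", 10, 15, "E", "LIG")]
    anchor_in = [_motif("P", 15, 30, "A", "ANCHOR")]
    anchor_out = [_motif("P", 16, 30, "A", "ANCHOR")]
    assert anchor_association(elm, anchor_in).associated["LIG"] == 1
    assert anchor_association(elm, anchor_out).associated["LIG"] == 0


def test_association_requires_same_protein():
    elm = [_motif("P", 10, 15, "E", "LIG")]
    anchor = [_motif("Q", 10, 15, "A", "ANCHOR")]
    assert anchor_association(elm, anchor).associated["LIG"] == 0


def test_association_matches_position_set_oracle(rng):
    """Counts equal a brute-force position-set intersection scan."""
    for _ in range(10):
        elms, anchors = [], []
        for i in range(15):
            pid = f"P{rng.integers(0, 3)}"
            s = int(rng.integers(1, 80))
            e = s + int(rng.integers(0, 10))
            cat = ELM_CATEGORIES[int(rng.integers(0, 4))]
            elms.append(_motif(pid, s, e, f"E{i}", cat))
        for i in range(8):
            pid = f"P{rng.integers(0, 3)}"
            s = int(rng.integers(1, 80))
            anchors.append(_motif(pid, s, s + int(rng.integers(0, 20)), f"A{i}", "ANCHOR"))
        counts = anchor_association(elms, anchors)
        anchor_pos = {
            (a.protein_id, p) for a in anchors for p in range(a.start, a.end + 1)
        }
        for cat in ELM_CATEGORIES:
            expect_total = sum(1 for e in elms if e.category == cat)
            expect_assoc = sum(
                1
                for e in elms
                if e.category == cat
                and any(
                    (e.protein_id, p) in anchor_pos
                    for p in range(e.start, e.end + 1)
                )
            )
            assert counts.totals[cat] == expect_total
            assert counts.associated[cat] == expect_assoc


# ----------------------------------------------------------------------
# chi-squared goodness of fit
# ----------------------------------------------------------------------
def test_chisq_worked_example_from_published_counts():
    """ELM category mix within binding regions for the intron-less MycL
    paralog: totals 13/30/40/2, associated 0/9/3/1 -> p = 0.025."""
    counts = CategoryCounts(
        totals={"CLV": 13, "LIG": 30, "MOD": 40, "TRG": 2},
        associated={"CLV": 0, "LIG": 9, "MOD": 3, "TRG": 1},
    )
    res = category_chisq(counts)
    assert res.statistic == pytest.approx(9.394, abs=5e-4)
    # printed as 0.025; exact recomputation gives 0.0245
    assert res.p_value == pytest.approx(0.025, abs=1e-3)
    assert res.p_value == pytest.approx(0.02448, abs=5e-5)


def test_chisq_zero_iff_proportional():
    counts = CategoryCounts(
        totals={"CLV": 10, "LIG": 20, "MOD": 30, "TRG": 40},
        associated={"CLV": 1, "LIG": 2, "MOD": 3, "TRG": 4},
    )
    res = category_chisq(counts)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chisq_matches_direct_formula(rng):
    for _ in range(20):
        totals = {c: int(rng.integers(1, 50)) for c in ELM_CATEGORIES}
        associated = {
            c: int(rng.integers(0, totals[c] + 1)) for c in ELM_CATEGORIES
        }
        counts = CategoryCounts(totals=dict(totals), associated=dict(associated))
        if counts.A == 0:
            continue
        N, A = counts.N, counts.A
        expect = sum(
            (associated[c] - A * totals[c] / N) ** 2 / (A * totals[c] / N)
            for c in ELM_CATEGORIES
        )
        assert category_chisq(counts).statistic == pytest.approx(expect)


def test_counts_validation():
    with pytest.raises(InconsistentCountsError):
        CategoryCounts(totals={"CLV": 0}, associated={"CLV": 1})


# ----------------------------------------------------------------------
# Fisher exact tests
# ----------------------------------------------------------------------
def test_fisher_worked_examples_from_published_counts():
    mycl2 = CategoryCounts(
        totals={"CLV": 13, "LIG": 30, "MOD": 40, "TRG": 2},
        associated={"CLV": 0, "LIG": 9, "MOD": 3, "TRG": 1},
    )
    assert round(category_fisher(mycl2, "LIG").p_value, 2) == 0.01
    mycl1 = CategoryCounts(
        totals={"CLV": 13, "LIG": 33, "MOD": 32, "TRG": 2},
        associated={"CLV": 4, "LIG": 14, "MOD": 9, "TRG": 2},
    )
    assert round(category_fisher(mycl1, "LIG").p_value, 2) == 0.36


def test_fisher_identical_row_proportions_give_p_one():
    counts = CategoryCounts(
        totals={"CLV": 10, "LIG": 10, "MOD": 0, "TRG": 0},
        associated={"CLV": 5, "LIG": 5, "MOD": 0, "TRG": 0},
    )
    assert category_fisher(counts, "LIG").p_value == pytest.approx(1.0)


def test_fisher_matches_hypergeometric_enumeration(rng):
    """Two-tailed p equals the sum of hypergeometric point probabilities not
    exceeding the observed table's, for random tables with N <= 100."""
    for _ in range(25):
        n_lig = int(rng.integers(1, 40))
        n_rest = int(rng.integers(1, 60))
        A = int(rng.integers(1, n_lig + n_rest))
        a = int(rng.integers(max(0, A - n_rest), min(n_lig, A) + 1))
        counts = CategoryCounts(
            totals={"LIG": n_lig, "CLV": n_rest, "MOD": 0, "TRG": 0},
            associated={"LIG": a, "CLV": A - a, "MOD": 0, "TRG": 0},
        )
        N = n_lig + n_rest
        p_obs = hypergeom.pmf(a, N, n_lig, A)
        support = range(max(0, A - n_rest), min(n_lig, A) + 1)
        expect = sum(
            hypergeom.pmf(k, N, n_lig, A)
            for k in support
            if hypergeom.pmf(k, N, n_lig, A) <= p_obs * (1 + 1e-9)
        )
        assert category_fisher(counts, "LIG").p_value == pytest.approx(
            min(expect, 1.0)
        )


# ----------------------------------------------------------------------
# ANCHOR coverage summaries
# ----------------------------------------------------------------------
def test_anchor_summary_published_values():
    a1 = [_motif("P12524", 1, 132, "A1", "ANCHOR")]
    assert anchor_summary(a1, 364) == (1, 132, 36)
    a2 = [_motif("P12525", 100, 168, "A1", "ANCHOR")]
    assert anchor_summary(a2, 357) == (1, 69, 19)


def test_anchor_summary_merges_overlaps_and_handles_empty():
    regions = [
        _motif("P", 1, 10, "A1", "ANCHOR"),
        _motif("P", 5, 14, "A2", "ANCHOR"),
    ]
    count, residues, pct = anchor_summary(regions, 100)
    assert (count, residues, pct) == (2, 14, 14)
    assert anchor_summary([], 100) == (0, 0, 0)


def test_anchor_summary_region_beyond_sequence_raises():
    with pytest.raises(UnknownIdError):
        anchor_summary([_motif("P", 90, 120, "A", "ANCHOR")], 100)


def test_merge_intervals():
    assert merge_intervals([(5, 9), (1, 3), (8, 12)]) == [(1, 3), (5, 12)]
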