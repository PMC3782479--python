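# disotree

Dendrograms and motif statistics from protein intrinsic-disorder profiles.

Transcription factors and other intrinsically disordered proteins evolve
quickly at the sequence level while their *disorder profile* — the
per-residue propensity to lack stable structure — can stay recognisably
conserved. `disotree` is a toolkit for exploiting that signal in protein
families (the motivating case is the Myc family): it substitutes
per-residue disorder scores from any predictor into a multiple protein
alignment, builds distance-based dendrograms from the resulting profile
matrix with multiscale-bootstrap support, compares dendrograms produced
by different predictors, and runs the companion statistics on linear
motif (ELM) and predicted binding-region (ANCHOR) annotations.

## What it computes

**Aligned disorder matrix.** Given an alignment with rows g₁…g_N over L
columns and a disorder profile per ungapped sequence, scores are placed
at their alignment columns; gap cells are missing. Distances between
proteins are gap-aware Euclidean:

    d(i,j) = sqrt( (L / |S_ij|) · Σ_{c ∈ S_ij} (x_ic − x_jc)² )

over the columns S_ij scored in both rows (an alternative mode treats
missing as 0). Trees come from deterministic agglomerative clustering
(average linkage by default).

**Multiscale bootstrap support.** At each scale r, ⌈r·L⌉ columns are
resampled with replacement and the tree rebuilt; BP_r is the fraction of
replicates containing each clade. With ψ_r = Φ⁻¹(1 − BP_r), the weighted
least-squares fit

    ψ_r ≈ v·√r + c/√r,    AU = 1 − Φ(v − c)

gives the approximately unbiased support per edge; BP is BP_r at r = 1,
and standard errors follow from the binomial counts by the delta method.
Defaults: 10 scales r = 0.5 … 1.4, 1,000 replicates each.

**Dendrogram comparison.** For leaves A, B, d(A,B) is the number of edges
on the tree path between them. Two trees are compared by the Pearson
correlation ρ of their leaf-pair path-distance vectors over shared
leaves, with combined dissimilarity d′ = 1 − m·ρ where m is the leaf-set
overlap fraction; tree sets are ordered for heat maps by clustering the
d′ matrix.

**Motif statistics.** One-sided Mann–Whitney tests for higher disorder
at ELM-covered positions (union of intervals, never double-counted; the
per-motif variant deliberately keeps covered scores inside the reference
set), chi-squared goodness-of-fit of the ANCHOR-associated ELM category
mix against the overall mix (df = 3), per-category two-tailed Fisher
exact tests, and ANCHOR coverage summaries. `conserve` adds BLOSUM62
mean-score-per-residue and identity for named alignment regions, plus
the strict score > 140 / length > 300 BLASTP candidate filter.

**Synthetic families.** `synthgen` generates clade-structured families
(piecewise-linear clade archetypes, truncated Gaussian residue noise,
indel-like gap runs, planted motifs with tunable enrichment odds ω) so
every stage runs and can be calibrated with no external data.

## Worked example

```python
from disotree import (FamilyConfig, generate_family, map_scores_to_alignment,
                      bootstrap_tree, clade_recovery, tree_correlation)

fam = generate_family(FamilyConfig(n_clades=3, proteins_per_clade=4, seed=11))
matrix = map_scores_to_alignment(fam.alignment, fam.profiles)
tree, supports = bootstrap_tree(matrix, n_boot=1000, seed=11)

for s in sorted(supports, key=lambda s: s.edge_id):
    if s.clade in map(frozenset, fam.true_clades):
        print(f"clade {sorted(s.clade)}: AU={s.au:.0f}% BP={s.bp:.0f}%")

print("recovery:", clade_recovery(tree, fam.truth_tree, fam.true_clades))
sim = tree_correlation(tree, fam.truth_tree)
print(f"rho={sim.rho:.3f}  m={sim.m:.2f}  d'={sim.d_prime:.3f}")
```

prints

```
clade ['C1P1', 'C1P2', 'C1P3', 'C1P4']: AU=100% BP=100%
clade ['C2P1', 'C2P2', 'C2P3', 'C2P4']: AU=100% BP=100%
clade ['C3P1', 'C3P2', 'C3P3', 'C3P4']: AU=100% BP=100%
recovery: 1.0
rho=0.701  m=1.00  d'=0.299
```

Every true clade is recovered with full bootstrap support (the 10,000
column resamples never break a clade, so AU and BP are both 100%). The
tree-to-truth correlation is below 1 only because the ground-truth tree
arranges proteins *within* each clade arbitrarily while the inferred
within-clade structure follows the noise; the d′ = 0.299 quantifies that
residual disagreement.

The same pipeline is available from the shell:

```
disotree simulate --seed 11 --out-prefix fam
disotree tree --alignment fam.fasta --scores fam.scores.csv \
              --nboot 1000 --scales 0.5:1.4:0.1 --seed 11 --out tree.nwk
disotree compare tree.nwk fam.truth.nwk --out-matrix rho.csv
disotree elmstats --scores fam.scores.csv --elms fam.motifs.csv --out report.csv
```

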