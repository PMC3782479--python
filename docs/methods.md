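# Methods

## The disorder-profile comparison model

The package treats a protein's per-residue intrinsic-disorder profile —
scores in [0, 1], one per residue, from any predictor — as a comparable
character vector once profiles are placed on a common coordinate system.
That coordinate system is a multiple alignment: each score is assigned
to the alignment column of its residue, and gap cells are missing
values, never zeros. All downstream quantities are defined on this
aligned disorder matrix.

The implicit assumptions are the usual ones for profile phylogenetics:
the alignment is trusted (column homology is not re-estimated), scores
from one predictor are comparable across proteins, and alignment
columns are the exchangeable unit for resampling. Scores from
*different* predictors are never mixed in one matrix; different
predictors yield different trees, which are then compared at the tree
level.

## Distances, clustering, ties

Two gap policies are provided for the Euclidean distance between
protein rows:

* `pairwise_complete` (default): only columns scored in both rows
  enter, and the sum of squares is rescaled by L/|S_ij| so that pairs
  with sparse overlap are not artificially close. This treats a gap as
  "no observation".
* `gap_as_zero`: missing cells become 0 (fully ordered) and the plain
  Euclidean distance is taken. This treats a gap as "no disorder" and
  is kept for sensitivity analysis; the two agree exactly on gap-free
  data.

A pair of rows with no shared scored column is an error, not a silent
NaN.

Clustering is agglomerative (average linkage by default; complete and
single available) with merge heights equal to the linkage distance, so
average linkage yields the usual UPGMA ultrametric. Equal-distance ties
are broken deterministically by merging the pair whose clusters contain
the earliest input rows; the fully degenerate all-ties matrix therefore
produces a left-to-right caterpillar, and repeated runs are
bit-reproducible. The clusterer is written in-package because this tie
contract cannot be expressed through `scipy.cluster.hierarchy`; scipy is
used as an independent cross-check on tie-free instances in the tests.

## Multiscale bootstrap support

For scales r (default 0.5, 0.6, …, 1.4) and B replicates per scale
(default 1,000, i.e. 10,000 trees in total), each replicate resamples
⌈r·L⌉ alignment columns with replacement and rebuilds the tree. Support
is accounted per rooted clade (the cluster below each internal edge,
singletons excluded): BP_r is the fraction of replicate trees containing
the clade, and BP = BP_r at r = 1.

The approximately unbiased (AU) value comes from the
signed-distance/curvature model: with ψ_r = Φ⁻¹(1 − BP_r), weighted
least squares fits ψ_r ≈ v√r + c/√r, where weights are the inverse delta-method
variances B·φ(ψ_r)²/(BP_r(1−BP_r)), and AU = 1 − Φ(v − c). Standard
errors for BP come from the binomial count and for AU from the fitted
(v, c) covariance through the normal density. Numerical policy:

* scales where the clade appeared in no or all replicates carry no
  information about the curve and are dropped from the fit;
* a clade unanimous at (essentially) every scale is pinned to AU = 0 or
  100 with its standard error flagged degenerate rather than fitted;
* a flat BP_r = 0.5 curve fits to v = c = 0 and AU = 50 exactly.

One point worth stating because it is easy to get wrong: a literally
constant BP_r ≠ 0.5 across scales is *outside* the model (v√r + c/√r
cannot be constant unless v = c = 0), and the fit then drives AU toward
50 rather than toward BP. AU ≈ BP holds when the fitted curvature c is
zero, not when BP_r is flat.

All replicate streams derive from one integer seed via
`numpy.random.SeedSequence`, so runs are reproducible and independent of
protein input order (column resampling does not involve the rows).

## Tree comparison

Leaf-pair distances are topological edge counts on the rooted tree as
drawn — both root edges count, so for ((A,B),C) the A–C path has three
edges. Unrooting would change some counts by one; the rooted convention
matches trees produced by clustering, which have a meaningful root.
Pearson correlation ρ is computed over the leaf pairs shared by both
trees; the overlap fraction m is Jaccard, |A∩B|/|A∪B|, which reduces to
1 (so d′ = 1 − ρ) when the trees cover the same proteins — the case the
combined score was designed for — while staying defined for partial
overlap. A zero-variance path vector makes ρ undefined; it is reported
as 0 with an explicit flag and a warning, never as a silent NaN. Heat-map
axis order for a set of trees is the leaf order of average-linkage
clustering of the d′ matrix, inheriting the deterministic tie rule (an
all-identical set keeps input order).

## Motif statistics

The global enrichment question — are ELM-covered positions more
disordered? — is answered by a one-sided Mann–Whitney test of the union
of covered positions (a position under several motifs counts once)
against all other scored positions, pooled over proteins. The per-motif
variant compares a motif's covered positions against the *full* score
set including themselves; this keeps the reference identical across
motifs and attenuates evidence toward the null, so in the enrichment
regime it understates significance (the attenuation also means it can
sit slightly *below* the strict-complement p when there is no
enrichment; it is conservative exactly where it matters).

Mann–Whitney p-values are exact whenever exact is affordable: a full
tie-aware permutation enumeration when the number of label splits is at
most 2·10⁵ (with a direct closed enumeration when one group is a single
observation), the classical no-ties exact distribution for tie-free
groups up to size 50, and the normal approximation with tie correction
otherwise.

ELM×ANCHOR association uses the weakest consistent overlap rule — an
ELM is ANCHOR-associated iff it shares ≥ 1 residue with any ANCHOR
region on the same protein — which reproduces the published MycL worked
examples. The category-mix test is a one-sample chi-squared
goodness-of-fit of the associated counts (a_CLV, a_LIG, a_MOD, a_TRG)
against expectations A·n_c/N, df = 3, no continuity correction; a 2×4
contingency reading does not reproduce the published p-value and is not
used. Per-category Fisher tests are two-tailed by the point-probability
rule on the {category, rest} × {associated, not} table. No
multiple-testing correction is applied by default, matching the original
analysis; the CLI can append clearly-labelled Benjamini–Hochberg columns
as an extension. ANCHOR coverage merges overlapping regions before
counting residues and reports an integer percent of sequence length.

## Conservation scores

Region scores against a reference row use BLOSUM62 (via Biopython's
`substitution_matrices`, the canonical matrix) averaged per residue over
columns where both rows carry residues — a gap is not a substitution and
contributes to neither numerator nor denominator. Identity fractions use
the same column rule. The BLASTP candidate filter keeps hits with score
strictly greater than 140 *and* aligned length strictly greater than 300
residues; whether "score" is the bit score is configurable (the default
reads the tabular bitscore column).

## The bundled predictor

External predictors are the intended score source and enter as CSV.
The bundled predictor exists so the pipeline is self-contained and
transparent: the score of residue i is a logistic squash (midpoint at
the scale mean, steepness 4) of the mean TOP-IDP propensity over a
centred window (default 21 residues, truncated at the termini; unknown
residue X scores the scale mean). It is deterministic,
reverse-covariant, and a substitution can only move scores within half a
window of its position — window means are computed per slice rather than
via prefix sums precisely so that property holds to the last bit. It
makes no claim of numeric agreement with VSL2P, VLXT, IUPred or any
published predictor; mutation scans reproduce the analysis pattern
(mutant minus wild-type difference profiles), not any published curve.

## The synthetic generator

`synthgen` emulates what the pipeline needs from real data and nothing
more: clade-conserved disorder architecture. Each clade has a
piecewise-linear archetype (default 8 segments over 300 columns) built
as a shared mid-range base curve plus clade offsets rescaled so the mean
absolute between-clade difference is δ (default 0.4). A protein is its
archetype plus i.i.d. N(0, σ²) residue noise (default σ = 0.04, i.e.
σ/δ = 0.1) truncated to [0, 1] — truncation, not wrapping, which biases
scores slightly inward near 0 and 1. Gaps are contiguous runs with
geometric lengths (mean 3 columns) at an expected cell rate of 0.02,
mimicking indels rather than salt-and-pepper missingness. Residue
letters are sampled from disorder- or order-promoting pools according to
the local score so sequence-side tools see plausible composition; the
letters carry no phylogenetic signal of their own. Motifs (default 36 of
length 8, i.e. three per protein at the default family size) are planted
with start weights ω^[window mean > 0.5], so ω = 1 is the uniform null
and larger ω enriches motifs in disordered regions.

What the generator does *not* emulate: realistic disorder score
autocorrelation structure from any particular predictor, alignment
error, heterotachy, within-clade phylogenetic substructure (all proteins
in a clade are exchangeable draws around one archetype — the ground
truth tree's within-clade arrangement is arbitrary), or the heavy ELM
density of real annotation tables. Tests passing on synthetic families
therefore demonstrate algorithmic correctness and calibration under the
stated model, not performance on real proteomes.

## Known limitations

* **The position-level rank test is anti-conservative on autocorrelated
  profiles.** The Mann–Whitney test treats positions as exchangeable,
  but disorder profiles are smooth and motifs are contiguous windows, so
  under uniform motif placement the effective number of independent
  covered units is closer to the number of motifs than the number of
  covered positions. The calibration simulation in the acceptance script
  computes this directly: at nominal α = 0.01 the uniform-planting
  rejection rate is roughly twenty-fold inflated under the default
  family conditions. This is a property of the test design itself — the
  same caveat applies to any position-level enrichment p-value of this
  kind, including those this analysis pattern is drawn from — and is the
  reason the power figure (computed in the same script) should be read
  together with the null rejection rate, not alone.
* AU values are extrapolations from a two-parameter fit; for clades with
  BP_r unanimous at every scale they are pinned, not estimated, and the
  degenerate flag should be checked before quoting a standard error.
* `pairwise_complete` rescaling assumes scores missing at random given
  the alignment; systematically gappier clades will have noisier (not
  biased) distances.
* Path-distance correlation compares topologies only; branch-length
  information is deliberately ignored.
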