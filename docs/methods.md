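# Methods

This note documents the models, conventions and design choices behind
`barcodegap`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Reduced-database construction

A species is *barcoded* when at least one of its per-library flags (BOLD,
GenBank) is true for the requested source set (union semantics). The
reduced catalog preserves input order; reducing a community drops entries
whose taxon lacks a barcode but keeps every sampled (site, season) key, so
a sample emptied by the reduction is carried forward as azoic rather than
silently vanishing. Coverage percentages are `100·n_barcoded/n_total`,
carried unrounded with a half-up integer rounding for display only. Two
per-phylum statistics are emitted because published gap figures are quoted
under either denominator: within-phylum coverage, and each phylum's share
of the missing pool (the shares sum to 100%).

Taxon joining is exact string matching after normalization (trim, collapse
internal whitespace, binomial case fold). Synonym resolution against
taxonomic registries is deliberately out of scope; names must be
pre-reconciled.

## Descriptors and AMBI

Richness counts taxa with abundance strictly greater than zero. Shannon
diversity uses log base 2 by default (the convention of the standard AMBI
desktop software); the base is recorded in every record, and every
downstream correlation is base-invariant. Communities that look like
presence/absence data (all positive abundances equal to 1) are accepted
with a logged warning: S is unaffected, but H and AMBI then degrade to
richness-driven values because the abundance weighting is uninformative.

AMBI is the abundance-weighted mean of the group weights (0, 1.5, 3, 4.5,
6) over ecological groups I–V. Individuals of not-assigned (NA) species
count toward the not-assigned fraction but are excluded from the weighted
mean by renormalization; the value is flagged invalid when that fraction
exceeds 20% (threshold configurable). Azoic samples take the sentinel
coefficient 7 with S = H = 0, an M-AMBI score of 0 and class Bad — an
explicit flag rather than a silent number.

## M-AMBI

The multivariate index is computed deterministically: the (AMBI, H, S)
rows of all scored samples plus the two reference rows are standardized
column-wise (zero mean, unit variance over the assembled matrix); the
correlation matrix is eigen-decomposed (PCA, no rotation); all rows are
projected onto the leading `min(n_factors, rank)` components (default 3);
the score is `t = ((x − bad)·(high − bad)) / |high − bad|²` in the
projected space, so the bad reference maps to exactly 0 and the high
reference to exactly 1; scores are clamped to [0, 1] with the raw value
retained. With all three factors the projection is an isometry of the
standardized space and the score equals the direct standardized-space
computation; component sign ambiguity cancels in `t` by construction.

Reference conditions default to bad = (AMBI 6, H 0, S 0) and high =
(AMBI 0, 1.15·max H, 1.15·max S) over the dataset; the 15% inflation keeps
observed samples below the pristine anchor, and explicit references
override the rule. By default one shared reference pair serves both the
morphological and the reduced run, so the comparison isolates the
library-gap effect rather than a shift of the scale. Class boundaries
default to 0.77 / 0.53 / 0.39 / 0.20 (WFD intercalibration values in
common use for transitional waters) and are fully configurable, since the
exact values used by any particular closed-source assessment run are not
recoverable; published class grids can instead be ingested directly and
compared with `class_divergence`. Boundary scores belong to the upper
class.

A zero-variance column across samples + references makes standardization
undefined and raises a degenerate-input error; with valid references this
requires deliberately malformed anchors, but the guard keeps the failure
explicit.

## Divergence and correlation

Class divergence uses the fixed ordinal encoding Bad=0 … High=4. Any
nonzero signed distance `ordinal(reduced) − ordinal(morphological)` is a
divergence; better/worse counts, the percentage (unrounded + half-up
display), and the maximum absolute distance are reported, the last so that
multi-class jumps are surfaced rather than averaged away. Note the
packaged Apulian grid itself contains one two-class jump (site 8, fall:
Moderate vs Bad) even though such jumps are often described as
single-class. Correlations are Pearson r with the two-sided t-transform
p-value (n − 2 df), computed per season by default with pooling behind a
flag, and reported unadjusted — no multiple-testing correction is applied,
matching common practice for this handful of planned comparisons.

## Sequence analysis

**Consensus.** Per column of a per-species alignment: the unique most
frequent non-gap symbol wins if its frequency among non-gap symbols
exceeds the majority threshold (default 0.5); ties at the maximum resolve
to the minimal IUPAC code covering the tied symbols' base sets; all-gap
columns are dropped. The operation is idempotent, and a single sequence
returns itself.

**K2P.** Sites with a gap or ambiguity code in either sequence are
excluded pairwise (conservative; no probabilistic resolution). With P and
Q the transition and transversion proportions over retained sites,
`K = −½ ln((1−2P−Q)√(1−2Q))`; a non-positive log argument marks the pair
saturated, and saturated pairs block tree building with an explicit error
listing them.

**Neighbor joining.** Standard Saitou–Nei with the Q-criterion, exact on
additive matrices. Negative branch-length estimates are clamped to zero
with the deficit transferred to the sibling so each joined pair keeps its
pairwise distance; Q-ties break deterministically on the lowest pair of
original label indices; the result is unrooted (trifurcating root) for
four or more taxa.

**ML-PTP delimitation.** The number of substitutions accumulating on a
branch is modeled as exponential with one rate for speciation
(between-species) branches and one for within-species branches. A
delimitation assigns each leaf to a species clade; edges strictly inside
species clades are within-species, all others between-species; rates are
profiled at their MLEs, giving the class log-likelihood `n(log(n/Σb) − 1)`.
Three conventions matter:

- *Minimum branch length.* Edges ≤ `min_branch` (default 1e-7) are
  excluded from the likelihood. Identical sequences produce zero-length
  NJ edges, and including them lets the within-species rate diverge, which
  collapses the ML solution into pathological oversplitting; exclusion is
  the convention of modern PTP implementations.
- *Search.* For fixed rates the optimal delimitation is found exactly by
  an O(n) tree dynamic program (each node either becomes a species crown
  or delegates to its children). The search alternates this DP with rate
  re-estimation from every initialization induced by splitting the sorted
  edge lengths, and additionally runs best-improvement hill climbing over
  split/merge moves from the all-singleton, single-cluster and seeded
  random starting states. Plain hill climbing alone was observed to stall
  in local optima; the combined search matches exhaustive enumeration on
  every small tree tested. All tie-breaks are deterministic (lexicographic
  node order), so results are reproducible given the seed.
- *Model comparison.* The two-rate fit is compared with the one-rate null
  by AIC with change-point parameter counting: the alternative spends 2
  rate parameters plus one boundary parameter per cluster beyond the
  first, the null spends 1. Counting only the two rates would ignore that
  the partition itself is optimized and would essentially never prefer
  the null, even for structureless trees. When the null wins, the
  returned assignment collapses to a single cluster (disable with
  `collapse_if_null=False` to inspect the best two-rate partition).

Unrooted input is midpoint-rooted with a logged notice (delimitation
depends on rooting); polytomies are resolved with zero-length edges.
Bayesian per-cluster support values are not produced — this is a
deterministic ML counterpart of the MCMC implementations, not a
reimplementation of them.

**Partition scoring.** A true species is *separated* iff its leaves form
exactly one cluster containing no other species' leaves; merges and splits
are enumerated. **Primer matching** scans the forward primer along the
target and the reverse primer along the target's reverse complement, with
IUPAC-aware compatibility (codes match iff their base sets intersect); the
pair is found when both ends hit within the mismatch budget (default 3).
The packaged Folmer pair ships alongside a degenerate variant whose
inosine positions are encoded as N, inosine having no IUPAC letter.

## Synthetic data

The generators emulate the survey structure the analysis assumes; they are
first-class, tested code, not fixtures.

**Catalog.** Default preset: 82 species over six phyla with Mollusca /
Annelida / Arthropoda at 40 / 28 / 25% of species (≈93% combined) and
per-phylum union barcode probabilities 0.58 / 0.65 / 0.73 (0.64 for the
minor phyla) — the coverage regime of a regional Mediterranean checklist.
The per-phylum probability governs the union ("at least one library");
barcoded species are then attributed to BOLD and/or GenBank with at least
one flag set. Ecological groups are drawn from a fixed mixture
(I…V, NA = 25/20/20/15/10/10%).

**Communities.** 15 sites × 2 seasons over an even disturbance gradient in
[0, 1]. Species tolerance anchors to ecological group (I→0.0, II→0.25,
III→0.5, IV→0.75, V→1.0; NA species get a latent uniform tolerance);
occupancy probability is a Gaussian kernel (width 0.25, peak 0.7) of the
site-tolerance mismatch, so clean sites fill with groups I–II and
disturbed sites with IV–V and expected AMBI rises monotonically with
disturbance. Abundances are log-normal (μ_log 2, σ_log 1), rounded up to
at least one individual — the abundance distribution of real surveys is
not otherwise constrained, and the parameter is configurable.

**Sequences.** A random-join species tree with shifted-exponential edge
lengths `0.3·s + Exp(0.7·s)` at the between-species scale s (default 0.05
substitutions/site): exponential speciation waiting times with a floor at
30% of the scale, encoding the empirical barcoding gap — real congeneric
COI sequences essentially never sit at ~0 divergence, and without the
floor a sizable minority of simulated species would be unresolvable by any
method, which is not the regime the module exists to emulate. Each species
tip carries a within-species coalescent of accessions (scale 0.0025, i.e.
a 20:1 rate ratio; 3 accessions per species by default). Sequences evolve
along the tree under K80 (κ = 4, 600 bp) with exact transition
probabilities. The generator returns the alignment, the true
accession→species map and the generating tree.

What the generators do **not** emulate: sequencing reads, PCR/primer bias,
chimeras or OTU-clustering error (the analysis operates on species lists
and reference sequences, not reads); spatial autocorrelation between
sites; seasonal turnover beyond independent draws; rate heterogeneity
across sites or lineages (K80 is homogeneous). Passing tests therefore
demonstrate correctness of the computations and qualitative behavior of
the workflow under its own assumptions, not performance on real
metabarcoding data.

**Determinism.** Every generator output is a pure function of its
configuration; a single global seed fans out to fixed per-stage child
streams (catalog / community / sequences), so stages can be regenerated
independently. The pipeline writes a run log with seed, configuration hash
and library versions, and identical inputs reproduce byte-identical
outputs.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: the
published 15-site grid; 82-species catalogs; 50-replicate survey
simulations; NJ exactness over all 123 unrooted shapes with ≤6 leaves;
delimitation-vs-enumeration on trees with ≤8 leaves; and 20-replicate
recovery experiments at 10 species × 3 accessions × 600 bp. Live-database
quantities (which species have barcodes today, which primers are recorded)
are inputs, not computations, and are covered by the calibration and
property tests instead.

## Known limitations

- M-AMBI reproduces the published construction, not the numeric output of
  any specific closed-source assessment tool; class grids from such tools
  are treated as data.
- NJ bootstrap support values and Bayesian delimitation supports are out
  of scope; no multiple sequence alignment or ML tree search is performed
  (pre-aligned input, externally built trees accepted as newick).
- Presence/absence inputs yield richness-driven H and AMBI (warned, not
  rejected).
- The PTP model assumes a single within-species rate shared across
  species; strongly heterogeneous within-species depths will bias the
  delimitation.
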