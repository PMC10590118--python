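# Methods

## The modeled experiment

Cord-blood monocytes differentiated with M-CSF in the presence or absence of
human lactoferrin (hLF), each arm with or without 24 h LPS stimulation, give
a 2×2 design with four conditions (uM, uM_LPS, hlf, hlf_LPS) measured on the
same four donors (paired). The package analyses a normalized log2 expression
matrix from such a design; array preprocessing (background correction, RMA
summarization) is upstream and out of scope, though a quantile-normalization
utility is provided for the synthetic path.

## Differential expression

Per gene, ordinary least squares on a treatment-coded design with condition
effects and (by default) donor indicator columns. Donor blocking is on by
default because the donors are paired across all four conditions; a flag
drops it. Contrasts are linear combinations of condition coefficients; the
four analysed are hlf-vs-uM, uM_LPS-vs-uM, hlf_LPS-vs-uM_LPS, and
hlf_LPS-vs-hlf.

Variance moderation follows the standard empirical-Bayes hierarchy
s² ~ s₀²·F(d, d₀): hyperparameters (d₀, s₀²) come from closed-form moment
matching of log s² (mean/variance expressed in digamma/trigamma, trigamma
inverted by Newton iteration), the posterior variance is the df-weighted
blend (d₀s₀² + d s²)/(d₀ + d), and the moderated t uses d + d₀ degrees of
freedom. This matches the reference R implementation (limma) to ~1e-6 on
shared fixtures (see tests). Degenerate cases: s² = 0 for some genes →
replaced by the smallest positive s² × 1e-8 with a warning; all s² exactly
equal → d₀ = ∞ and s₀² equals the common value; all s² zero → fall back to
the unmoderated statistic with a warning.

DEG selection uses strict inequalities — FDR < 0.05 and logFC > 0.58 or
< −0.58 — reading the cutoff phrasing literally ("below/above"); both
thresholds are configurable, and `lfc_cut=0` reproduces the
no-fold-change-cutoff sensitivity analysis. Benjamini–Hochberg adjustment is
delegated to statsmodels and cross-checked against a brute-force step-up in
the tests. The targeted per-gene comparison uses one-way ANOVA plus Tukey
HSD (studentized range, via scipy).

## Pathway over-representation

The background for each contrast is expression-matched: genes are ranked by
mean expression over all samples and split into 10 equal-frequency bins
(configurable); the background is the union of bins containing at least one
DEG, always a superset of the DEG. "Similar expression values" is not
quantified in the source workflow; equal-frequency binning is this package's
operationalization. Over-representation is the upper-tail hypergeometric
probability P(X ≥ k) with BH adjustment across sets; an ORA rather than a
ranked GSEA statistic is used because the analysis thresholds input genes
(FDR < 0.1), which is the over-representation idiom. Theme comparison joins
per-contrast enrichments over the union of sets significant anywhere
(adjusted p < 0.1), tagging direction by the sign of the mean logFC of a
set's member DEG (ties → "mixed"). The chord-diagram adjacency keeps DEG
with |logFC| strictly above 2.5.

## Regulator networks

The co-expression network is built on the DEG union: pairwise Pearson |r|,
soft-thresholded by the smallest integer power β ∈ 1..20 whose weighted
degree distribution achieves a scale-free fit R² ≥ 0.85 (R² of
log₁₀ frequency on log₁₀ binned degree, 10 bins). If no power qualifies —
common at n = 16 samples with strongly condition-driven correlation — the
power with maximal R² is used and logged; note that soft-thresholding is
monotone, so the retained top-5 % edge set is independent of β. Retention
keeps exactly ceil(0.05 × candidate pairs) edges network-wide before
restricting to regulator-incident edges. Regulator targets are network
neighbours.

Target enrichment among DE genes (differential p < 0.05) is a one-sided
Fisher exact test (hypergeometric upper tail); significance requires
BH-adjusted p < 0.05 and q < 0.2, where q is a Storey q-value with π₀
estimated at λ = 0.5 (the two columns would be redundant if both were BH).
The composite importance score is this package's own definition — the sum of
the rank-normalized −log₁₀ p of the differential and enrichment components,
each mapped to [0, 1] across regulators, hence a score in [0, 2] invariant
to monotone transformations of either p-vector. It is declared in the
metadata of every score table it appears in. Attribution gives a regulator
one point per gene shared between its target set and a pathway's genes in
the chord adjacency; the top-5 regulators per pathway are kept with ties
broken by composite score, then gene symbol. External PPI edge lists are
filtered at confidence ≥ 0.900 (inclusive).

## Interaction propensity

Macrophage-side expression is the per-condition mean across donors of the
annotation-filtered DEG (cytokines for the soluble channel, membrane
proteins for the physical channel); partner-side expression is a reference
profile of immune cell types. Both matrices are z-standardized per gene
across their own columns with the sample SD (n−1) — conditions on one side,
cell types on the other — which is what makes the products comparable
"arbitrary units". The propensity of condition c toward cell type t is the
sum over channel edges of z_macro(a, c)·z_cell(b, t); physical edges are
undirected and counted in both orientations, soluble edges are
macrophage-outgoing (an inbound mode exists behind a flag). Edges whose
genes are missing from either matrix are skipped — never imputed as zero —
and tallied in a coverage report (used + skipped = total, always). Scores
are reported as deltas against the untreated reference condition.

The driver decomposition attributes a condition difference to macrophage
genes: per gene, (z_a − z_b) times the partner z, summed over incident edges
and cell types. The signed sum reproduces the total delta exactly
(bilinearity), but because every standardized partner row sums to zero
across cell types, the signed sum is identically ~0 when the partner matrix
is fully standardized; the table therefore also reports a contribution
magnitude (per-cell-type contributions summed in absolute value), and ranks
drivers by interaction count (number of partner cell types with raw
expression > 0 of at least one partner), then magnitude.

## Synthetic data

The generator draws y = baseline + donor + condition effect + noise on the
log2 scale: baselines uniform on [4, 12] (so matched-background binning has
structure), gene-specific donor effects N(0, 0.5²) shared across a donor's
four samples, residual noise N(0, 0.3²), and condition effects planted on
two free axes — a treatment effect applied identically to hlf and hlf_LPS
(40 genes by default) and an LPS response applied to uM_LPS only (97 genes)
— with magnitudes uniform on [1.0, 3.5] (outside the 0.58 detection band)
and random signs. The defaults are ~1/10 the scale of the modeled study
(2000 genes against the arrays' ~20k measured genes, DEG counts in
proportion); per-gene variance and effect-size distributions are
conventional choices, not estimates from the deposited arrays. The
hlf_LPS-vs-uM_LPS truth is the difference of the two axes, mirroring the
biology in which treatment blocks the LPS response; hlf_LPS-vs-hlf is an
exact null.

The planted hub-regulator module emulates a dominant regulator program (as
the coherent cell-cycle program reported for hLF): one regulator with a
top-of-range effect whose 30 targets carry its donor effect, exact condition
effect and condition-centred noise plus independent noise N(0, 0.3²).
Centring the shared noise within conditions keeps each target's population
logFC equal to the truth-table entry (a shared uncentred draw would move a
whole module's sample logFC coherently); the module is sized and coupled so
it is the strongest co-expression structure, which is the property the
recovery tests assert. Annotation classes (cytokine 10 %, membrane 20 %,
regulator 8 %, innate 15 %) are sampled independently and non-disjointly;
module regulators are forced into the regulator class.

Gene sets: one planted set per free axis (80 % of members drawn from that
contrast's true DEG), the rest uniform. Interactions: physical edges between
membrane genes, soluble edges from cytokine-class genes to synthetic
receptors present only in the partner profiles; partner profiles cover six
cell types, each gene expressed with probability 0.7 at uniform(1, 10).
Optional planted interaction edges use one-hot condition effects
(macrophage side) and one-hot cell-type profiles (partner side); with ddof=1
z-scores, a one-hot across 4 conditions yields a z-difference of exactly 2
and a one-hot across n cell types yields (n−1)/√n, so the expected
propensity shift per planted edge is 2(n−1)/√n — stored in the ground truth
and used by the planted-shift checks. Planted shifts are restricted to the
uM/uM_LPS axis to preserve the hlf = hlf_LPS identity, and default to zero
edges.

What the generator does not emulate: probe-level artifacts, batch effects,
correlated gene-gene noise outside planted modules, heavy-tailed intensity
distributions, or realistic pathway overlap structure. Passing tests
therefore demonstrate the correctness and calibration of the pipeline's
machinery under the stated model, not performance on real arrays.

## Problem sizes and determinism

Default analyses run on 2000 genes × 16 samples; replicate-based checks use
20 replicates (hub recovery, null behaviour, planted-set ranking), 200
datasets of 20 genes for hyperparameter recovery, and a few hundred
randomized cases for each exact oracle — sizes chosen so the whole suite and
the acceptance script each run in well under a minute on one core. All
randomness flows from explicit seeds (generator streams are keyed by
[seed, stage]); identical configurations reproduce every output
byte-for-byte, and each output TSV carries its generating config hash.

## Known limitations

- The composite regulator score is a package-defined statistic; it is
  monotone and scale-free but not numerically comparable to the score of the
  original regulator-enrichment package it is inspired by.
- With 16 samples the scale-free fit rarely reaches R² ≥ 0.85; the logged
  fallback applies (inconsequential for the retained edge set, see above).
- Under the planted complete null, BH at level α still rejects ≥ 1 gene in
  ~α of replicates (measured ~2 % here after the fold-change filter), so
  "zero DEG" holds in most but not every replicate — matching multiple-
  testing theory rather than a hard guarantee.
- Propensity scores are descriptive (arbitrary units); no significance is
  attached, and receptor-complex stoichiometry is not modeled.
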