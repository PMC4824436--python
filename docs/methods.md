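# Methods

## Scope and data model

The pipeline analyzes a samples × metabolites matrix of non-negative
ion intensities from GC-TOF-MS profiling, with one genotype label per
sample. Missing measurements are carried as NaN and never conflated
with zero. Group statistics require ≥ 2 replicates per genotype;
metabolite names are matched exactly after whitespace trimming (no
fuzzy matching, to prevent silent aliasing of near-synonyms such as
"Malate" / "Malic acid" — annotation tables must use the pipeline's
names).

## Preprocessing chain

Order: presence filter → half-minimum imputation → mTIC normalization.
The literature this pipeline follows does not fix whether normalization
precedes the presence rule; filtering first means per-sample totals are
computed over the reported panel only, and imputation before
normalization keeps every sample's total defined.

**Presence filter.** A metabolite is reported only if observed in at
least `min_fraction` (default 0.8) of the samples of *every* genotype
group — the standard reporting rule for identified GC-MS compounds.
The operation is idempotent, preserves column order, and an empty
result is an error rather than an empty table.

**Half-minimum imputation.** Residual missing cells (≤ 20% per group
after the filter) are replaced by half the metabolite's minimum
observed value across all samples — the usual left-censoring convention
for values below the detection limit.

**mTIC normalization.** Each sample is divided by its summed intensity
over all identified metabolites, removing per-sample loading and
instrument drift, then multiplied by the cohort mean of the per-sample
totals so values keep their original magnitude (`tic_rescale="none"`
yields pure fractions). After normalization every sample has an
identical metabolite sum (relative tolerance 1e-9). Note the exact
invariances: the *fraction* matrix is invariant to rescaling any single
input sample; with the mean rescale the output additionally changes by
a single global constant (the mean of totals is data-dependent).
Normalization preserves within-sample ratios and leaves two-group
*t*-tests and fold changes unchanged under any global rescaling.

## Differential abundance

Per metabolite, a two-sided two-sample Student's *t*-test with pooled
variance (the classical reading of "Student's t-test"; Welch is
available via `welch=True` but is not the default) and the fold change
as the ratio of arithmetic group means, test over reference. Degenerate
variance is handled by convention: if neither group varies, P = 1 for
equal means and 0 otherwise. Primary significance is the raw P < α
(default 0.05) with no multiple-testing correction, matching the
workflow this pipeline reproduces; `results_to_frame` adds a
Benjamini–Hochberg q-value column for modern reuse, which never drives
the primary calls. Reciprocity holds exactly: swapping test and
reference flips the fold change to its reciprocal and leaves P
unchanged.

## PCA and hierarchical clustering

PCA is computed by SVD of the column-centered matrix; the default
scaling is autoscaling (unit variance per metabolite), appropriate when
intensities span orders of magnitude, with `scaling="center"` for
covariance PCA. Signs follow a deterministic convention (the
largest-magnitude loading of each component is positive). Variance
fractions equal the covariance eigenvalue fractions.

Hierarchical clustering uses d = 1 − Spearman rank correlation
(midranks for ties) and average (UPGMA) linkage, along either axis.
The dendrogram is rank-invariant under monotone transforms and is
exported as Newick with merge heights as cumulative node depths. A
constant profile has no defined rank correlation and is a named error.
Tie-breaking among equal-height merges follows the linkage
implementation's ordering; merge sequences are verified against a naive
O(n³) algorithm on dissimilarity matrices with distinct entries.

## Gene-dosage template matching

Pavlidis template matching scores each metabolite by Pearson
correlation between its profile and a template laid over an ordered
genotype series. By default the template value for a genotype is
broadcast to every replicate and r is computed over replicate-level
points, giving P from the *t* distribution with n − 2 df (n = total
replicates) — the convention of the original microarray implementation;
`means_only=True` correlates the per-genotype means directly. The
default templates (1, 0.5, 0) and (0, 0.5, 1) encode a linear
gene-dosage trend with the heterozygote at half the homozygote effect
on the log scale. A match requires r > 0 and P below the threshold, so
a metabolite can never match both monotone templates; constant profiles
are reported as degenerate and unmatched, never as NaN. r is invariant
to affine rescaling of the template, and reversing the genotype order
swaps the up and down clusters exactly.

## Two-layer metabolic network

Chemical similarity is the Tanimoto coefficient |A∩B|/|A∪B| on binary
substructure fingerprints; pairs at or above the cutoff (default 0.7)
become similarity edges. Precomputed fingerprints (hex-encoded bit
strings) are the canonical, fully reproducible path; when only SMILES
are given, Morgan circular fingerprints (radius 2, 1024 bits) are
computed and the scheme is recorded in the graph metadata, because edge
sets depend on the fingerprint scheme and different schemes are not
bit-compatible. Metabolites without structure stay in the network as
nodes but carry no similarity edges. The biochemical layer reads a
curated edge list of single-reaction metabolite pairs (the package
never calls a remote database); pairs with endpoints outside the cohort
are dropped with a log entry. A pair may carry both tags as two
parallel typed edges. Node styling encodes the differential results:
size is affine in |log₂ FC| clipped to [10, 60] display units, and
color (red up / blue down) is assigned only to significant metabolites.
Exports: SIF, a node-attribute TSV, and GraphML; SIF carries topology
and tags only, GraphML round-trips all attributes.

## Cross-genotype consensus

The discordance ratio counts metabolites significant *between* two
mutant alleles over the panel size; a percentage at or below 100·α is
flagged as within systematic error (the comparison's own
false-positive budget), the study logic for treating two null alleles
as biologically equivalent. Allele-specific sets are plain set algebra
over the two mutant-vs-wild-type significant sets. The consensus call
requires significance in both the mutant-vs-WT and the
deficient-vs-rescue comparison with the same direction; both
comparisons must be explicitly oriented with the gene-deficient
condition as the test group, since direction agreement is meaningless
otherwise. Output is ordered by summed −log₁₀ P (a stable ranking
device only), ties by name.

## Synthetic-data generator

The generator reproduces the target design: 5 genotypes (WT, het, hom,
rescue, gal4 = second null allele) × 6 replicates × 109 metabolites.
Intensities are `mean · exp(ε)` with ε ~ N(−σ²/2, σ²) and
σ² = ln(1 + cv²) — multiplicative lognormal noise with the given CV on
the natural scale (default 0.2, a typical between-replicate CV for
GC-TOF intensities), strictly positive values, expectation equal to the
truth mean, and exact truth means at cv = 0. Baselines are lognormal
across metabolites (natural-log mean 10, sd 1.5, spanning roughly two
to three orders of magnitude).

Planted classes (defaults; all effects ±1 log₂ unless noted):

* **dosage_down** (17) / **dosage_up** (9) — monotone across
  WT → het → hom with the het at half the hom effect on the log scale
  (linear in functional gene copies); cluster sizes mirror the
  17-member down and 9-member up dosage clusters of the motivating
  study.
* **consensus** (3; two down, one up) — altered concordantly in both
  null alleles (hom, gal4) and restored to the WT mean in rescue,
  emulating the methionine / ornithine / glucose-6-phosphate pattern.
* **marker** (1) — log₂ FC = 4.71 (~26-fold) in every non-WT genotype,
  emulating a genetic-background artifact (the eye-pigment marker)
  rather than a gene effect.

Two structural choices matter for error control under mTIC
normalization, which assumes the compounds carrying most of the total
signal are stable: planted-effect metabolites draw their baselines from
the same lognormal truncated below the cohort's 80th abundance
percentile, and the marker is a trace compound (baseline offset −3 on
the natural log). Without these, a planted metabolite that happens to
draw a dominant baseline share shifts whole-sample totals and leaks
apparent (false) effects into every null metabolite — a real hazard of
total-signal normalization that the motivating design avoids because
its extreme fold changes occur in trace compounds. With them, measured
type-I error among nulls stays near the nominal 5% both in pure null
simulations and in planted runs.

An optional missing-completely-at-random mask (`missing_rate`)
exercises the presence filter and imputation. The truth record (class
per metabolite, per-genotype true means, config echo) is emitted as a
sidecar so tests never reach into generator internals. Same seed, same
table, bitwise.

What the generator does *not* emulate: retention-time or batch drift,
correlated metabolite families (covariance is diagonal on the log
scale), missingness that depends on abundance (left-censoring), or
sample-loading variation. Passing recovery tests therefore demonstrate
correctness of the statistical machinery at the design point, not
robustness to those real-data complications.

## Simulation study sizes and expected operating characteristics

The recovery study (tests and `scripts/acceptance.py`) uses 20
simulated studies at the default design plus 10 null-configuration
studies (≥ 1000 null metabolite-tests) for type-I calibration. At n = 6,
cv = 0.2, |log₂ effect| = 1, differential recovery of planted effects
is ≈ 100% with null-simulation type-I ≈ 5%. Template matching at
P < 0.01 recovers the planted 17 + 9 monotone sets nearly always, but
the event "zero of the 79 null metabolites matches either template"
has probability 0.99⁷⁹ ≈ 0.45 per study from the noise floor alone
(the two mirrored templates jointly consume the full two-sided 1%
tail), so across 20 studies a majority with zero null matches is not
expected; the acceptance suite reports this operating characteristic
as measured. The consensus call recovers the 3-member planted class
with no null metabolite called in ~90% of studies.

## Numerical conventions and degenerate inputs

* P-values printed as "0.000" in the packaged three-decimal table are
  right-censored at their upper bound 5e-4 by the loader (the printed
  precision admits nothing finer), which preserves the printed ordering
  and the scientific-notation entries' ranks.
* Extreme-rank reports break all ties by metabolite name; dendrogram
  and network exports are deterministically ordered, so reruns are
  bit-identical.
* Zero within-group variance, zero reference means, constant profiles
  under rank correlation or autoscaling, empty fingerprints, empty
  filter results, and unoriented consensus comparisons are all explicit
  named errors (or flagged conventions), never silent NaN propagation.
* Seeds: every stochastic path is driven by one integer seed through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.

## Known limitations

* Fingerprint-dependent similarity edges: Morgan(2, 1024) is a
  different scheme from server-side substructure fingerprints used in
  older studies; edge sets are reproducible within a scheme only.
* The pooled t-test is applied on the natural intensity scale (no log
  transform), matching the reproduced workflow; heavy-tailed noise
  slightly perturbs nominal error rates at small n.
* The reaction-pair layer is only as complete as its curated input
  list; the packaged list is a small demonstration covering the
  methionine-salvage and central-carbon metabolites of the fixture
  panel.
* No effect-size shrinkage, moderated statistics, or supervised
  projections (PLS-DA) — out of scope by design.
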