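# Methods

This note documents the models and procedures implemented in `coenhance`,
the parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the numerical conventions a user relying on exact
reproducibility should know.

## Coordinate and interval conventions

All coordinates are 0-based half-open (the BED convention). GTF input
(1-based closed) is converted on read; exonic gene length is the length of
the union of a gene's exons. The transcription start site (TSS) is
`tx_start` on the + strand and `tx_end − 1` on the − strand.

The distance between two non-overlapping intervals is the gap between their
closest edges (0 on any overlap, including a shared boundary). Edge-gap is
used for all co-occupancy calls; midpoint-to-midpoint distance is available
behind the `anchor="midpoint"` flag, and midpoint-to-TSS distance anchors
gene assignment, which needs a point. Sorting ties break by
(chrom, start, end, name) for reproducibility.

## Region annotation

A region is **TSS-proximal** when it overlaps, by at least 1 bp, the
strand-aware promoter window spanning 2 kb upstream through 1 kb downstream
of any TSS; otherwise **intragenic** when it overlaps any gene body;
otherwise **intergenic**. Precedence is fixed in that order, so the three
category counts always sum to the number of input regions. The ≥ 1 bp
overlap semantics (rather than midpoint containment) is the conservative
interval reading of "located within" a window; the window sizes are
arguments and can be changed per call.

## Superenhancer calling

Candidate enhancer peaks are processed in three steps:

1. **Promoter exclusion with embedded rescue.** Peaks overlapping any
   TSS ± 2 kb window are excluded — unless, after provisionally stitching
   *all* peaks at the stitching gap, the excluded peak's stitched region
   also contains at least one non-promoter peak. Such a peak sits inside a
   larger acetylation-positive chromatin domain and is rescued.
2. **Stitching and scoring.** Retained peaks are stitched at ±12.5 kb
   (edge gap ≤ 12,500 bp merges; a shared boundary counts as gap 0). Each
   stitched region is scored by `max(ChIP_pm − input_pm, 0)`, where both
   tracks are first scaled to per-million mapped reads — input subtraction
   is meaningless across library sizes otherwise. Ranks are descending by
   score, ties broken by genomic position.
3. **Inflection cutoff.** Scores are sorted ascending and both rank index
   and score rescaled to [0, 1]. The ascending score curve of real and
   simulated enhancer landscapes is convex (a hockey stick), and the
   conventional geometric cutoff is the point where a line of slope 1 is
   tangent to the curve from below — the index minimizing `y − x`, i.e. the
   point of maximal distance below the diagonal. Enhancers with score
   strictly **above** the cutoff score are super (the tangent point itself
   remains a typical enhancer). Degenerate inputs (fewer than 3 regions, or
   a flat score vector) call nothing super.

The partition is invariant under positive rescaling of all scores and under
adding a constant, since both axes are unit-rescaled.

Note that on a pure-noise score vector (no planted superenhancers) the
tangent rule still flags the top tail of the curve — empirically ~5–15% of
regions depending on the realized curve shape. This is inherent to the
geometry, not a bug: the cutoff always exists, and "no separable regime"
manifests as the called set carrying no unusual signal rather than as an
empty call.

## Chromatin states

States are a pure function of three overlap flags (≥ 1 bp against each mark
peak set, or an optional minimum-fraction-of-region threshold):
H3K4me3⁺ dominates and yields `promoter_like` regardless of the other
marks — mirroring the exclusion of H3K4me3⁺ regions from enhancer classes;
then `active_enhancer` = K4me1⁺/K27ac⁺, `poised_enhancer` = K4me1⁺/K27ac⁻,
and `unmarked` otherwise. Classification is order-independent and conserves
region counts.

## Co-occupancy statistics

A region of set A is **co-bound** when its nearest set-B region lies at
edge distance strictly below the threshold (default 1,000 bp; overlap = 0
qualifies) — the literal reading of "< 1 kb". The co-bound fraction is
monotone non-decreasing in the threshold.

Venn-style summaries group A and B regions into merged co-bound clusters
(connected components under the same distance rule); a cluster containing
both factors counts once as *shared*, which resolves many-to-one peak
multiplicity without double counting. `A_only + shared_A = |A|` always
holds, and symmetrically for B.

Overlap significance is the exact hypergeometric upper tail
`P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` with the shared denominator N (all
active E/SEs, in the intended application), evaluated through scipy's
log-gamma-based distribution functions for numerical stability; fold
enrichment is `k/(Kn/N)`.

Signal enrichment between region classes is compared by the Mann–Whitney
rank-sum test: exact by full enumeration of all C(n+m, n) labelings when
n + m ≤ 12 (ties handled through half-counted pairs), otherwise the normal
approximation with tie correction and a 0.5 continuity correction. The
two-sided p doubles the smaller tail (capped at 1) in both modes; at the
switch-over size the two branches agree within 0.01 on one-sided tails.

## Profile matrices

Read-distribution profiles center a window (default 3 kb) on each region
midpoint `floor((start+end)/2)` and cut it into fixed bins (default
100 bp). Raw bin values are signal sums; BPM multiplies by 10⁶ / total
mapped reads (deepTools-compatible semantics — the quantity is named but
not defined by its common usage). The source description of this procedure
mixes a 3-kb and a 6-kb window; 3 kb is the default here and the window is
an argument, so either reading is available. Bins clipped by a chromosome
edge are zero-filled and flagged.

## Differential expression

The expression stage is a deliberately simple two-group negative-binomial
Wald test, not a reimplementation of DESeq2's estimator chain:

- **Size factors**: median-of-ratios over genes with nonzero counts in all
  samples.
- **Dispersion** α per gene by method of moments on size-factor-normalized
  counts — for `y = K/s`, `Var(y) = μ·E[1/s] + αμ²` — estimated within each
  group, averaged where defined, floored at 1e-8. A fixed-α mode exists for
  simulations. No shrinkage toward a mean–dispersion trend.
- **Fold change**: `log2(μ₂/μ₁)` of normalized group means; a group with
  mean zero is replaced by a pseudo-mean (default 0.125 normalized counts)
  and flagged, keeping the estimate finite. Fold changes are raw, not
  shrunken, and the signature threshold (|FC| ≥ 1.2) applies on the linear
  scale.
- **Inference**: Wald statistic `log2FC/SE` with the delta-method SE from
  the NB variance, tested two-sided against a **t reference with n₁+n₂−2
  degrees of freedom**. With ~10 samples per group the moment dispersion is
  noisy and the normal reference is measurably anticonservative (null
  type-I ≈ 0.069 at the 0.05 level in our calibration runs); the t
  reference restores calibration (≈ 0.051). Benjamini–Hochberg step-up
  q-values follow.
- **Signatures**: genes at q < 0.05 and linear |FC| ≥ 1.2, split by sign
  into disjoint up/down lists.

Median-of-ratios normalization assumes most genes are not differentially
expressed; strongly unbalanced (one-directional) differential expression
induces composition bias that attenuates fold-change estimates. The
synthetic generator plants signs at random, which keeps the factors
identifiable; on real data with suspected global shifts a spike-in or
control-gene normalization would be needed instead.

Unsupervised sample clustering takes the top-500 genes by standard
deviation, computes 1 − Pearson r distances (constant rows dropped with a
warning) and applies UPGMA (average linkage) through scipy's hierarchical
clustering.

Cross-species signature tracking maps gene symbols through a two-column
ortholog table; 1:many mappings either keep all targets (default) or the
first listed, and unmapped genes are reported, never silently dropped.

## Preranked GSEA

The enrichment score is the classical weighted Kolmogorov–Smirnov running
sum: hits add `|score|^p / Σ_hits|score|^p` (p = 1 by default; 0 and 2
supported), misses subtract `1/(N − N_hits)`; ES is the extremum of maximal
absolute deviation, sign retained, with positive deviation winning exact
ties. The leading edge is the hits at or before the positive extremum (at
or after, for negative ES). With p = 0 the running sum closes exactly at 0,
and ES is invariant to positive rescaling of the ranking scores.

Significance uses **gene-label permutation**: size-matched random sets
drawn (seeded) from the ranking. This is the appropriate null for
signatures applied to an external ranking, where no per-sample phenotype
labels exist to permute. Per set:

- `p_perm = (1 + #{|ES_null| ≥ |ES_obs|}) / (n_perm + 1)` — the magnitude
  tail over the full null with add-one smoothing. This form is uniform
  under the null and attains its minimum `1/(n_perm+1)` for a maximally
  enriched set; a sign-restricted tail over the same denominator would be
  bounded near 0.5 and cannot be calibrated, which is why the magnitude
  form is used.
- `NES = ES / mean(|ES_null| of the matching sign)` — sign-stratified, as
  positive and negative null deviations have different scales.
- FDR q by the sign-stratified ratio-of-tails scheme over the pooled
  normalized null versus the observed NES values, capped at 1.

The default ranking metric for a differential-expression contrast is the
Wald statistic (configurable); `n_perm` defaults to 1,000 with a mandatory
seed.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed); the master seed
fans out to per-stage child streams (`default_rng([seed, stage_id])`) so
stages can be regenerated independently. Each generator emits a truth table
covering every planted object exactly once.

- **Genome**: uniformly placed non-overlapping genes (2–20 kb spans,
  Bernoulli strands, biotypes drawn from a configurable mix including
  rRNA/miRNA/pseudogene classes so the sanitization filters are exercised).
- **Co-occupancy**: co-bound A peaks get a B partner at edge gap
  Uniform{0..999}; solo peaks sit ≥ 5× the distance threshold from the
  other factor, in disjoint 20-kb slots, so truth labels are unambiguous
  and the planted fraction is recovered exactly up to rounding.
- **Superenhancers**: planted clusters of 3–6 constituent peaks with
  consecutive gaps well inside the 12.5-kb stitching range, at 10× (default)
  the typical per-bp ChIP density of the isolated ordinary enhancers; the
  input track is flat background with Poisson jitter on 10-kb bins.
  Ordinary-enhancer densities carry mild log-normal jitter (σ = 0.25).
- **Counts**: NB counts with log-normal baselines (median ≈ 90 normalized
  counts, clipped to [2, 5000]), uniform library-size factors in
  [0.7, 1.4], a configurable fraction of genes carrying |log2FC| = 2 with
  random sign, and gene sets where planted sets draw 80% of members from
  same-direction DE genes and decoys are uniform.

Default sizes reflect the intended desk-scale study conditions: 1,000 peaks
per factor for co-occupancy, 100 ordinary enhancers with 5 planted
superenhancer clusters, and 2,000 genes × 10 samples per group with
dispersion 0.1 for expression. The test suite and the acceptance script run
these sizes with 10–20 seed replicates each.

What the generators do **not** emulate: read-level data (no FASTQ/BAM, no
fragment-length or GC models), realistic genome sequence, peak-width and
signal-shape heterogeneity of real ChIP-seq, mean–dispersion trends and
outlier genes of real RNA-seq, or correlated gene sets. Passing recovery
tests therefore demonstrates the correctness of the estimators under the
stated models — not robustness to the full messiness of real sequencing
data; the upstream alignment/peak-calling steps those would require are out
of scope.

## Gene assignment for set-enrichment input

Bound regions are linked to genes by midpoint-to-TSS distance (ties by
gene_id), and global top-N gene lists are formed by ascending distance with
first-occurrence deduplication. This is a deliberate, documented stand-in
for assignment scores produced by annotation tools whose ranking statistic
is not reproducible from their outputs; the distance heuristic is flagged
in the relevant docstrings.

## Reproducibility and numerics

- All stochastic stages take explicit integer seeds; identical inputs and
  seed give byte-identical outputs (fixed float formats in TSV/JSON, no
  timestamps in the run manifest; the manifest's SHA-256 checksums make a
  rerun comparable byte for byte).
- Degenerate inputs are handled by declared rules rather than errors where
  a sensible value exists: empty interval sets stitch to empty; all-zero
  samples get TPM 0 with a warning; flat score vectors call no
  superenhancers; empty signature directions are skipped with a warning.
- Validation errors (malformed lines, inconsistent parameters) name the
  offending line or key; the CLI fails fast before any stage runs and exits
  2 on validation errors, 1 on runtime errors.

## Known limitations

- The NB test has no dispersion or fold-change shrinkage and no
  independent filtering; at very small counts its power is below DESeq2's.
- The hypergeometric overlap treats regions as exchangeable units; it does
  not model region length or genome-wide placement bias.
- The inflection cutoff always produces a cut point, even on pure noise
  (see above); interpreting a superenhancer call requires the planted/real
  signal contrast, not the call alone.
- Only single-factor two-group designs are supported; no batch correction.
- bigWig/bigBed, liftover and BAM-level processing are out of scope.
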