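# coenhance

Desk-scale analysis toolkit for studying **cooperative enhancer regulation in
germinal-center (GC) B cells**: how two chromatin modifiers (an H3K27/H3K18
acetyltransferase and an H3K4 monomethyltransferase) co-occupy a shared
network of enhancers/superenhancers (E/SEs), and how their combined loss
disrupts a distinct transcriptional program.

The package is aimed at computational biologists who want each stage of such
an analysis as a tested, reusable library function rather than a chain of
one-off scripts:

- **Interval arithmetic and annotation** (`coenhance.intervals`) —
  BED3/BED6/narrowPeak/GTF readers, ±gap stitching, nearest-peak distances,
  and TSS-proximal (−2/+1 kb promoter window) / intragenic / intergenic
  region annotation.
- **Signal tracks** (`coenhance.tracks`) — bedGraph step functions, region
  sums, and binned read-distribution profiles around peak midpoints in bins
  per million (BPM = bin signal × 10⁶ / total mapped reads).
- **Superenhancer calling** (`coenhance.rose`) — ROSE-style: promoter
  exclusion with the embedded-peak rescue, ±12.5 kb stitching, ranking by
  input-subtracted ChIP signal, and the signal-vs-rank inflection cutoff
  (slope-1 tangent on the unit-rescaled curve).
- **Chromatin states** (`coenhance.chromstate`) — active
  (H3K4me1⁺/H3K4me3⁻/H3K27ac⁺) vs poised (H3K4me1⁺/H3K4me3⁻/H3K27ac⁻)
  enhancer classification from histone-mark peak sets.
- **Co-occupancy statistics** (`coenhance.cooccupancy`) — co-bound calls at
  < 1 kb edge distance, shared/unique (Venn) summaries, upper-tail
  hypergeometric overlap tests, Mann–Whitney rank-sum comparisons.
- **Differential expression** (`coenhance.diffexpr`) — gene sanitization
  filters, TPM, median-of-ratios size factors, a two-group negative-binomial
  Wald test, Benjamini–Hochberg correction, and signature calling at
  FDR < 0.05 with linear |FC| ≥ 1.2; top-SD UPGMA sample clustering and
  cross-species ortholog mapping.
- **Preranked GSEA** (`coenhance.gsea`) — weighted Kolmogorov–Smirnov
  enrichment score, seeded gene-label permutation null, NES, FDR and
  leading edge, written from scratch.
- **Synthetic data with ground truth** (`coenhance.simulate`) — seeded
  generators for every input above: peak sets with a planted co-bound
  fraction, signal tracks with planted superenhancer clusters, mark sets
  with planted chromatin states, and NB count matrices with planted fold
  changes and planted enriched gene sets.

A `coenhance` command-line tool ties the stages into two end-to-end
workflows (chromatin co-occupancy; expression signatures) plus a fixture
simulator, with INI configuration and a reproducibility manifest.

## The statistics at the core

For a stitched enhancer region *r*, the ranking score is
`S(r) = max(ChIP_pm(r) − input_pm(r), 0)` with both tracks scaled to
per-million mapped reads; superenhancers are the regions whose score exceeds
the inflection of the ascending score-vs-rank curve (both axes rescaled to
[0, 1]; cutoff at the point of maximal distance below the diagonal, where a
slope-1 line is tangent).

Overlap of two region sets within a common denominator of *N* regions is
scored by the hypergeometric upper tail
`P(X ≥ k), X ~ Hypergeom(N, K, n)`, with fold enrichment `k / (Kn/N)`.

For gene *g* with normalized group means μ₁, μ₂ and moment dispersion α̂,
the Wald statistic is `W = log2(μ₂/μ₁) / SE`, with the delta-method
`SE² = Σⱼ(μ/sⱼ + α̂μ²)/(n²μ²ln²2)` summed over both groups, tested against a
t reference with n₁+n₂−2 degrees of freedom and BH-corrected.

The enrichment score of a gene set in a ranked list increments the running
sum by `|score|^p / Σ_hits |score|^p` at set members and decrements by
`1/(N − N_hits)` elsewhere; ES is the extremum of the running sum, NES
divides by the mean same-sign permutation-null |ES|.

## Worked example

```python
from coenhance.simulate import (simulate_cooccupancy, simulate_enhancer_peaks,
                                simulate_se_signal)
from coenhance.cooccupancy import classify_cobound
from coenhance.rose import rose_pipeline

chroms = {"chr1": 30_000_000, "chr2": 30_000_000}

sim = simulate_cooccupancy(chroms, n_a=1000, n_b=1000,
                           cobound_fraction=0.6, seed=1)
calls, frac = classify_cobound(sim.set_a, sim.set_b, max_dist=1000)
print(f"planted co-bound fraction 0.60, recovered {frac:.3f}")

peaks = simulate_enhancer_peaks(chroms, n=100, seed=1)
se = simulate_se_signal(peaks, se_clusters=5, enrichment_ratio=10.0, seed=1)
result, _ = rose_pipeline(se.peaks, se.chip, se.input_track, genes=[])
print(f"enhancers: {len(result.enhancers)}, called super: {result.n_super}, "
      f"cutoff score {result.cutoff_score:.2f}")
```

Output:

```
planted co-bound fraction 0.60, recovered 0.600
enhancers: 105, called super: 5, cutoff score 8232.40
```

The recovered fraction equals the planted one because every co-bound peak
pair is placed at < 1 kb and every solo peak at ≥ 5 kb from the other
factor; the five called superenhancers are exactly the five planted
clusters of 3–6 constituent peaks carrying 10× the typical signal density,
separated from the 100 ordinary enhancers by the inflection cutoff.

The same analyses run from the shell:

```sh
coenhance simulate --seed 1 --out fixture/
coenhance run --workflow chromatin  --fixture fixture/ --seed 1 --out chromatin_out/
coenhance run --workflow expression --fixture fixture/ --seed 1 --out expression_out/
```

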