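# Methods

This note documents the models and numerical choices behind `bsaqtl`, in
the order the pipeline applies them, together with what the simulator does
and does not emulate.

## Marker calling

Input is a per-site table of parental allele read counts. A site is kept
as a marker iff (a) each parent's total depth is at least `min_depth`
(default 5 reads; the threshold is applied to each parent separately, not
to the pooled parental depth), (b) each parent's major allele carries at
least `purity` of its reads (default 0.9), and (c) the two major alleles
differ. The purity filter exists because haploid yeast parents are
effectively homozygous: a 50/50 site is an alignment or contamination
artifact, not a genotype. Alleles are arbitrary strings, so indel alleles
are legal markers. Major-allele ties are broken lexicographically, which
is irrelevant in practice because a tied site fails the purity filter
(purity > 0.5 is enforced).

Raising `min_depth` can only shrink the called set (each site is judged
independently), and swapping the two parents swaps the allele columns of
the output — both properties are tested.

## The G statistic

For a marker with high-bulk counts (n₁, n₂) and low-bulk counts (n₃, n₄),
G = 2 Σ nᵢ ln(nᵢ/n̂ᵢ) with the independence expectations n̂ and the
0·ln 0 = 0 convention, computed via `scipy.special.xlogy` so zero cells
are exact, in natural logs. Equivalently G = 2N·I(allele; bulk) with I the
mutual information of the empirical joint — used as an independent oracle
in the tests, alongside scipy's contingency-table implementation.

A marker where either bulk has zero total depth has no defined G; it is
reported as NaN and excluded from the scan with a logged count. NaN rather
than 0, because "no data" must never be readable as "no association".

One-bulk designs use the goodness-of-fit form against the Mendelian 1:1
expectation, G = 2[n₁ ln(n₁/(f₀n)) + n₂ ln(n₂/((1−f₀)n))] with f₀ = 0.5.
This choice of contrast (selected bulk vs. expected segregation, rather
than vs. an unselected pool) is the natural single-pool analogue but is a
design choice of this package, not an externally fixed recipe.

With multiple biological replicates per bulk the default is to sum
replicate counts before computing G (`replicate_mode="pool"`): counts are
additive evidence. Averaging per-replicate G values
(`replicate_mode="mean"`) is available for designs where replicates are
suspected to differ systematically.

## Smoothing

G′ at a marker is the kernel-weighted mean of G over all markers within
half a window on the same chromosome; windows never cross chromosome ends.
The configured `width` (default 33,750 bp) is the **full** window span, so
the kernel support is ±16,875 bp around the focal marker — worth checking
when comparing against tools that parameterize the half-width. Kernels:
tricube (default), uniform, triangular. Distance is physical (bp), not
marker index, because marker density varies along the genome. The focal
marker always contributes weight 1, so G′ is defined for every marker and
is a convex combination of its window (min G ≤ G′ ≤ max G, tested).

## Null model and significance

G′ has no closed-form null, and its variance depends on depth, bulk size
and marker spacing, so the null is estimated empirically from the scan
itself: ln G′ ~ Normal(μ, σ), with μ the median and σ = 1.4826 × MAD of
the log values — estimators chosen for robustness to the QTL-bearing
right tail.

Robustness to the tail is not automatic, though. Selection distorts allele
frequencies along the *entire* chromosome carrying a QTL (linkage decays
over hundreds of kb in yeast), and on small genomes such markers can
approach half the sample — the breakdown point of the median. Two guards
keep the null fit clean:

1. **Allele-contrast screening.** Markers whose allele-frequency contrast
   (|f_H − f_L|, or 2|f_H − ½| in 1-bulk designs) exceeds 0.4 are presumed
   QTL-linked and excluded from the fit. At bulk size 50 and depth 40 the
   null drift of the contrast has s.d. ≈ 0.15, so 0.4 is ≈ 2.7 s.d.: under
   the null fewer than 1% of markers are screened, while markers tightly
   linked to a strong locus (contrast near 1) are reliably removed. The
   same idea appears in allele-frequency-difference filters used by other
   BSA packages. If screening would leave fewer than 20 markers, the full
   set is used.
2. **Hampel iteration.** The median/MAD fit is iterated, setting aside
   markers more than `trim_z` = 3 null s.d. above the location until
   stable. On QTL-free data this touches ~0.1% of markers and leaves the
   plain estimates essentially unchanged (`trim_z=None` restores the
   single-pass fit exactly).

P-values are upper-tail probabilities of the fitted log-normal (p = 1 for
G′ ≤ 0); q-values are Benjamini–Hochberg over all markers genome-wide —
one scan is one family of hypotheses, and BH remains valid under the
positive dependence that smoothing induces. Calibration is verified by
simulation: across 20 locus-free crosses (2,000 markers each) the mean
fraction of markers at q < 0.05 is ≈ 0.01.

All-identical G′ values make σ = 0 and raise a degenerate-null error
instructing the user to check the input, rather than producing p-values
from a zero-width null.

## Region calling

QTL regions are maximal runs of markers with q < α (default 0.05) on one
chromosome. Adjacent significant markers always share a run; runs
separated by a gap that contains non-significant markers are merged when
the gap is smaller than `merge_gap`, which defaults to the kernel width —
a dip narrower than the smoothing scale is an artifact of the smoother,
not evidence of two loci. The region peak is the marker with the highest
G′ (smallest coordinate on ties, for deterministic output); regions are
reported sorted by peak G′ descending with their marker counts, so users
can apply their own size filters (none is imposed).

## Variant effects

Variants are classified per (variant, gene model) pair against the genome:
outside every CDS → noncoding (splice sites, UTRs and promoters are
deliberately lumped here — only exonic consequences are annotated);
indels by length mod 3 (frameshift / in-frame); substitutions by rewriting
only the affected codons and translating them with the standard nuclear
code, reverse-complementing for minus-strand genes. Precedence when a
substitution spans codons: stop gain > stop loss > non-synonymous >
synonymous. The REF allele is checked against the genome and a mismatch is
a hard error naming the position. When gene models overlap, the per-parent
summary counts each variant once under its most severe class
(stop_gain > stop_loss > frameshift > nonsynonymous > inframe_indel >
synonymous > noncoding).

The classifier is validated against a brute-force oracle that rebuilds the
entire mutant CDS and diffs the full translated proteins, on randomized
genomes, gene models and variants of both strands.

Deleteriousness scores (e.g. from an external predictor) are consumed as a
precomputed (chrom, pos, alt, score) table and left-joined onto
non-synonymous variants only; they are never computed here.

## The cross simulator

The simulator generates the experiment the scan consumes, with ground
truth. Model and defaults:

- **Genome**: 16 chromosomes with the S. cerevisiae (SacCer3) lengths;
  markers on an even grid (default 1,500 bp spacing, the density of a
  typical yeast cross's ~48k markers over ~12 Mb).
- **Meiosis**: haploid segregants; per chromosome, crossover count ~
  Poisson with mean proportional to length at 3.5 × 10⁻⁶ per bp (≈ 0.35
  cM/kb, the yeast genome-wide average), breakpoints uniform, no
  interference. Every marker is P1/P2 with probability ½ marginally.
- **Phenotype**: y = Σ β·x + ε with x ∈ {0,1} the genotype at the marker
  nearest each causal locus, ε standard normal; β is in noise-s.d. units.
- **Selection**: bulks are the top-k and bottom-k segregants (k = 50 by
  default, matching a typical chronological-lifespan design), ties broken
  by segregant index.
- **Sequencing**: per marker/bulk/replicate, depth ~ Poisson(λ = 40) and
  P1-supporting reads ~ Binomial(depth, f(1−ε) + (1−f)ε) with f the bulk's
  true P1 frequency and ε = 0.001 a symmetric error rate.

Identical configurations (including seed) produce byte-identical output
files.

What it does not emulate: diploid designs, crossover interference,
segregation distortion, mapping bias, depth heterogeneity along the
genome (GC, repeats), or index hopping between bulks. Passing tests
therefore demonstrate correctness of the statistics under a clean additive
model, not robustness to every artifact of real sequencing data.

A subtlety the simulator makes visible: markers within a bulk are
correlated through linkage, so genome-wide averages of allele frequency
concentrate at the rate set by the number of segregants (and seeds), not
the number of markers. Tests of such averages use multi-seed means with
tolerances derived from the measured between-seed spread.

## Validation at study scale

The end-to-end properties are exercised at the scale of a realistic small
design — 500 segregants, bulks of 50, depth 40, markers every 1,500 bp,
kernel width 33,750 bp — kept to two chromosomes so the full suite runs in
seconds:

- **Null calibration**: 20 locus-free crosses; mean fraction of markers at
  q < 0.05 ≈ 0.01 (bound 0.08, generous because smoothing correlates
  neighbours).
- **Recovery**: one locus of 2 s.d. on one of two 750-kb chromosomes, 50
  seeds; the top region's peak falls within one kernel width of the locus
  in ≥ 90% of seeds and the locus-free chromosome stays region-free in
  ≥ 80%. Held-out validation over 400 additional seeds measured ≈ 0.99
  recovery and ≈ 0.84 specificity.

`scripts/acceptance.py` re-runs these computations from scratch for any
seed.

## Known limitations

- The empirical null assumes ln G′ is approximately normal away from QTLs;
  heavy local depth heterogeneity could violate this.
- The allele-contrast screen's 0.4 cutoff is calibrated for bulk sizes
  near 50 and depths near 40; very small bulks (larger drift) would push
  null contrasts toward the cutoff and merit a higher value.
- Region boundaries are the outermost significant markers; no confidence
  intervals are attached.
- The map dialect is this package's own (documented in `bsaqtl.io_map`)
  and is not guaranteed byte-compatible with other BSA pipelines' map
  files.
- One-bulk scans test against 1:1 segregation and are sensitive to any
  genome-wide segregation distortion.
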