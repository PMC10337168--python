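# Methods

## Scope and model

The package evaluates a genotype-by-low-pass-sequencing workflow in which
diploid individuals are sequenced at sub-5× depth with long reads, variants
are called and filtered, continuous allele dosages replace hard genotype
calls, and direct genomic values (DGVs) — linear genomic predictions
`DGV_it = µ_t + Σ_j x_j β_jt` with fixed allele-substitution effects — are
compared between the low-pass route and an array-genotype benchmark. A
parallel arm analyses per-CpG 5mC calls produced alongside the genotypes.

Every stage can run on synthetic data with known truth, which is how the
test suite and the acceptance script exercise the pipeline.

## Read accuracy

Per-read accuracy is derived from the SAM edit distance: the NM tag counts
substitutions plus inserted plus deleted bases, so the substitution-only
total mismatch score is `TMS = NM − ins − del` and accuracy is
`1 − TMS/read length`.

Numerical and interpretive choices:

- *Read length* is the full query length (soft clips included) by default.
  Aligned reference-consuming length is available via a flag; the choice
  matters only for clipped or indel-rich reads.
- TMS is clamped at zero: NM dialects differ between aligners, and a
  negative TMS indicates a tag convention, not negative error.
- The distribution mode is the midpoint of the highest-count fixed-width
  histogram bin (default width 0.001 on the accuracy scale, configurable),
  with ties broken toward the higher-accuracy bin. A kernel-density mode
  would depend on a bandwidth choice and is harder to test exactly.
- Secondary and supplementary alignments are excluded from accuracy and
  coverage; only primary alignments are counted.
- Read QC discards reads with length ≤ 150 bp (boundary exclusive for
  retention) or mean quality < 10 (boundary inclusive for retention);
  reads with no quality information fail the quality rule and are counted
  separately.

## Variant filtering

The depth-rescue rule retains a call iff depth > 2, or depth ≤ 2 and the
called alternate allele is present in the reference panel at that position.
Panel matching requires the alt allele, not just the coordinate. The
zygosity rule interprets "allele frequency" as the within-sample alt-read
fraction: heterozygous for 0 < AF < 0.90 (both boundaries exclusive),
homozygous-alt for AF ≥ 0.90, homozygous-ref at exactly 0. Multi-allelic
VCF records are split into per-alt calls before filtering; coordinates are
1-based throughout this module. Calls lacking a depth value are discarded
and counted under their own reason so the partition
retained + discarded = input always holds.

## Dosages

Reference-panel haplotype imputation (an LD-aware HMM in the real
workflow) is deliberately replaced by a per-site Bayesian posterior:
Hardy–Weinberg prior {(1−p)², 2p(1−p), p²} at panel allele frequency p,
binomial likelihood for the alt-read count with per-genotype alt
probabilities {ε, ½, 1−ε}, and the dosage allele DA as the posterior
mean. This is the package's central simplification. It preserves exactly
the properties the downstream analyses consume — a DA in [0, 2] whose
uncertainty shrinks with depth, prior-mean fallback (2p) at uncovered
sites so marker vectors stay complete, and the characteristic
heterozygote-vs-homozygote error asymmetry at low depth — while remaining
closed-form and exactly testable by enumeration. It does **not** capture
the accuracy boost that LD-based imputation extracts from neighbouring
sites, so absolute concordance and R² values at a given depth sit below
what a panel-imputation workflow achieves at the same depth; comparisons
*across* depths and the direction of all trends are preserved.

Likelihoods are computed in log space (the binomial coefficient cancels
across genotypes); ε = 0 is floored at 1e−12 so hard evidence remains
representable without NaNs. Genotypes are called from DA with the
heterozygote band 0.8 ≤ DA ≤ 1.2 (inclusive at both ends), and
concordance against array genotypes is categorised by |called − true|:
0 correct, 1 one-allele mismatch, 2 both alleles wrong.

## DGVs and closeness

Effects are fixed knowns keyed by (chrom, pos, alt); a marker present in
the effects table but absent from the input is an error rather than a
silent zero, because a dropped marker shifts every individual's DGV.
Markers whose ref/alt orientation is swapped relative to the effects
table are mirrored (DA → 2 − DA) with a logged count. The closeness
regression puts the array-based DGV on the left-hand side (benchmark
regressed on low-pass); Pearson and Spearman (average ranks for ties) are
symmetric so the direction only affects slope and intercept.

## Depth titration

The subsampling unit is the read: per individual,
`round(target/source × total reads)` reads are drawn uniformly without
replacement. For pileup count matrices this draw is realised as a
multivariate hypergeometric sample over the pooled (site, allele) read
population, which is distributionally identical to picking individual
reads. One master seed is spawned into independent substreams per
(depth, replicate) cell, so curves are byte-reproducible and a cell
failure (e.g. degenerate variance at extreme subsampling) is recorded
with NaN metrics and a reason instead of aborting the run. Replicates
default to 1 (the single-draw protocol); the property checks and the
acceptance script use 20.

## Methylation

bedMethyl input is 0-based half-open; GFF3 gene models (1-based closed)
are converted on load. Coverage filters are inclusive (≥ 4×, ≥ 7×, ≥ 10×),
so the filtered site sets are nested by construction. Bin methylation is
the coverage-weighted mean percent over fixed 500-bp bins (empty bins
omitted); cross-filter agreement is the Pearson correlation over bins
present in both profiles (≥ 3 shared bins required).

Feature annotation resolves overlaps by a fixed priority:
Promoter (within ± 3,000 bp of any TSS) > Exon > Intron > Downstream
(within 3,000 bp past the strand-appropriate gene end) > Distal
Intergenic. Promoter-first matches the promoter-centric reading of
methylation near genes; UTRs are collapsed into Exon. The downstream
window mirrors the promoter window; both are parameters. A "methylated
site" for breakdowns and profiles is a coverage-passing site with
percent modified above a configurable threshold, default 0 (any modified
read). TSS-distance profiles use strand-aware signed distance (negative =
upstream of the gene) to the nearest TSS, counted within ± 3,000 bp in
50-bp bins and normalised to sum to one.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not the sequencing physics:

- **Panel**: alt-allele frequencies Uniform(0.05, 0.5) by default — a
  common-variant spectrum like a genotyping chip's; genotypes
  Binomial(2, p) per site (HWE), independent across sites (no LD, since
  no stage here exploits LD); per-trait effects β ~ N(0, 1) and a normal
  intercept. The effect-size distribution is a stand-in — the national
  evaluation that supplies real allele-substitution effects does not
  publish theirs — and only sets the DGV scale, not any correlation or
  R² property.
- **Pileups**: coverage Poisson(λ) per (individual, site); each read
  reports the true allele with probability 1 − ε, uniform ε for both
  error directions. The symmetric-ε choice is the simplest model that
  produces the het-vs-hom concordance asymmetry at low depth.
- **Reads**: windows of a supplied reference with substitutions at rate
  ε per base and insertions/deletions each at a configurable per-base
  event rate (geometric lengths, mean 2); the emitted NM and CIGAR are
  constructed from the injected edits, and the per-read truth is kept
  for independent recounting. Defaults (length 5,000 ± 1,500 bp, min
  200 bp, quality 20) describe a routine long-read library.
- **Methylation**: true levels from a two-component Beta mixture
  (hypomethylated Beta(0.5, 10), hypermethylated Beta(10, 0.5), 70%
  hypermethylated — the bimodal CpG landscape of vertebrate genomes);
  coverage Poisson(12), modified reads Binomial(coverage, level);
  zero-coverage sites are omitted from bedMethyl output, as in real
  modified-base pipelines.

One global seed is expanded into per-stage substreams
(`numpy.random.SeedSequence`), so identical seeds give byte-identical
fixture files and stages can be regenerated independently.

What passing tests on this data do **not** show: performance under LD
(and hence the absolute accuracy of panel imputation), non-uniform or
context-dependent error profiles, mapping artefacts, pedigree structure,
or CpG-island spatial autocorrelation of methylation.

## Problem sizes

The test suite and acceptance script use simulation sizes chosen to make
sampling error small relative to the asserted effects while keeping runs
interactive: 200 individuals × 2,000 markers (10 seeds) for the
8×-recovery check, 100 × 1,000 with 20 replicates for the 0.5–2×
titration, 10,000–20,000 CpGs at λ = 12 for the methylation filters, and
1,000–2,000 reads for accuracy distributions. Distributional oracles are
asserted within three standard errors at n ≥ 10,000.

## Known limitations

- The per-site dosage posterior bounds achievable concordance below what
  LD-aware imputation reaches at equal depth (see *Dosages*); at 8× with
  ε = 0.01 its exact per-site mean-squared dosage error is ≈ 0.024,
  capping dosage-DGV vs truth-DGV R² near 0.94 under the default panel.
- Effects are treated as fixed and error-free; no shrinkage, reliability
  weighting or effect re-estimation.
- The read simulator has no homopolymer or strand-specific error
  structure, and quality scores are flat per read.
- Feature annotation assigns one category per site by the fixed priority
  above; sites in overlapping annotations of equal priority are not
  double-counted.
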