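# epiglows

Evaluation toolkit for **epi-genotype-by-low-pass sequencing**: genotyping
dairy cattle (or any diploid population) from sub-5× nanopore whole-genome
sequencing while simultaneously reading out 5mC methylation, and asking how
close the resulting genomic predictions come to those from SNP arrays.

It is aimed at animal-breeding and statistical-genetics practitioners who
want to quantify, under controlled conditions, what a low-pass long-read
workflow delivers at each stage: per-read basecalling accuracy, variant
filtering, allele dosages, direct genomic values, and methylation calls.

## What it computes

**Per-read accuracy from alignment edit distance.** For a mapped read with
edit-distance tag NM and CIGAR insertion/deletion totals, the
single-nucleotide total mismatch score is

```
TMS = NM − (length of insertions) − (length of deletions)
Accuracy = 1 − TMS / read length
```

Reads of length ≤ 150 bp or mean quality < 10 are discarded first.
Accuracy distributions are summarised by their median and histogram mode
(0.001-wide bins).

**Variant filtering.** Calls at depth ≤ 2 are discarded unless the called
alternate allele matches a reference-panel variant at that position
(depth rescue); a site is heterozygous when the within-sample alt-read
fraction lies strictly between 0 and 0.90, homozygous-alt at ≥ 0.90.

**Allele dosages.** Per site, a Hardy–Weinberg prior
{(1−p)², 2p(1−p), p²} is combined with a binomial read likelihood
(alt-read probability ε, ½, 1−ε for genotypes 0/1/2); the dosage allele
DA ∈ [0, 2] is the posterior mean. Genotypes are called from the dosage
with the conventional heterozygote band 0.8 ≤ DA ≤ 1.2, and scored
against array genotypes as correct / one-allele / both-allele mismatches.

**Direct genomic values.** For individual *i* and trait *t*,
`DGV_it = µ_t + Σ_j x_j β_jt`, with x_j an integer genotype or dosage and
β_jt fixed allele-substitution effects. Closeness between array-based and
low-pass DGVs is the R², intercept and slope of regressing the array
values on the low-pass values, plus Pearson and Spearman correlations.

**Depth titration.** Reads are subsampled uniformly without replacement to
target depths (0.5×, 1×, 1.5×, 2× by default) and the dosage → DGV →
closeness chain is re-run per replicate.

**Methylation.** bedMethyl 5mC calls are filtered at coverage ≥ 4×/7×/10×,
averaged (coverage-weighted) in 500-bp bins, compared across filters by
bin correlation, annotated to Promoter (TSS ± 3,000 bp) / Exon / Intron /
Downstream / Distal Intergenic, and profiled by distance to the nearest
TSS.

A synthetic-data module generates all inputs with known truth (HWE
genotypes, Poisson coverage, uniform base-error rate, SAM records with
consistent CIGAR/NM, Beta-mixture methylation levels), so every stage is
testable end to end.

## Worked example

```python
from epiglows import synthetic, dosage, dgv

panel = synthetic.simulate_panel(
    synthetic.PopulationConfig(n_individuals=200, n_snps=2000, seed=1))
ref, alt = synthetic.simulate_pileups(
    panel, synthetic.ReadSimConfig(target_depth=8.0, base_error_rate=0.01, seed=1))
_, da = dosage.posterior_matrix(ref, alt, panel.allele_freqs, error_rate=0.01)

effects = dgv.EffectsTable.from_panel(panel)
truth = dgv.compute_dgv(panel.genotype_matrix, effects, "MY")
lps = dgv.compute_dgv(da, effects, "MY")
m = dgv.closeness(truth, lps)
print(f"R2={m.r_squared:.3f} slope={m.slope:.3f} "
      f"intercept={m.intercept:.3f} spearman={m.spearman:.3f}")
```

prints

```
R2=0.913 slope=0.983 intercept=0.144 spearman=0.951
```

i.e. at 8× depth with a 1% base-error rate, DGVs built from posterior-mean
dosages explain 91% of the variance of the truth-genotype DGVs with an
essentially unbiased regression slope; the ranking of individuals is
nearly preserved (Spearman 0.95). At lower depths both R² and the
intercept degrade, which the titration module quantifies.

The same stages are exposed as a CLI:

```bash
epiglows summarize            # per-kit depth/variant summary of the bundled table
epiglows simulate --individuals 100 --snps 1000 --depth 2 --out counts.tsv
epiglows dose counts.tsv --error-rate 0.01
epiglows titrate --depths 0.5,1.0,1.5,2.0 --replicates 20 --seed 7
epiglows run config.yml       # full pipeline with provenance manifest
```

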