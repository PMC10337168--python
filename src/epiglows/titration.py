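"""Depth titration: subsample reads and re-score dosage -> DGV closeness.

Mirrors the downsampling experiment in which reads are drawn uniformly
at random (without replacement) from each sample to hit target mean
depths (0.5x, 1.0x, 1.5x, 2.0x by default), and the whole
dosage -> DGV -> closeness chain is re-run on each subsample. The
subsampling unit is the read, so per-site coverage varies naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dgv import EffectsTable, closeness, compute_dgv
from .dosage import concordance, da_to_genotype, posterior_matrix
from .synthetic import TruePanel

__all__ = ["TitrationPlan", "subsample_reads", "subsample_counts", "titration_curve",
           "aggregate_curve"]


@dataclass(frozen=True)
class TitrationPlan:
    """Target depths (fold-coverage), replicate count and master seed."""

    target_depths: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(d <= 0 for d in self.target_depths):
            raise ValueError("target depths must be positive")


def subsample_reads(reads, target_depth: float, source_depth: float, seed: int):
    """Uniform without-replacement subsample of an explicit read set.

    The retained count is ``round(target/source * n_reads)``; at
    target == source all reads are kept. Deterministic per seed, and
    the result is always a subset of the input.
    """
    if target_depth > source_depth:
        raise ValueError(
            f"target depth {target_depth} exceeds source depth {source_depth}")
    reads = list(reads)
    k = int(round(target_depth / source_depth * len(reads)))
    if k == len(reads):
        return reads
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=k, replace=False))
    return [reads[i] for i in idx]


def subsample_counts(
    ref_counts: np.ndarray, alt_counts: np.ndarray,
    target_depth: float, source_depth: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample pileup read counts uniformly without replacement.

    Per individual, ``round(target/source * total reads)`` reads are
    drawn from the pooled (site, allele) read population via a
    multivariate hypergeometric draw — exactly the distribution of a
    uniform without-replacement pick over individual reads.
    """
    if target_depth > source_depth:
        raise ValueError(
            f"target depth {target_depth} exceeds source depth {source_depth}")
    frac = target_depth / source_depth
    n_ind, n_sites = ref_counts.shape
    out_ref = np.empty_like(ref_counts)
    out_alt = np.empty_like(alt_counts)
    for i in range(n_ind):
        colors = np.concatenate([ref_counts[i], alt_counts[i]])
        total = int(colors.sum())
        k = int(round(frac * total))
        if k >= total:
            out_ref[i], out_alt[i] = ref_counts[i], alt_counts[i]
            continue
        draw = rng.multivariate_hypergeometric(colors, k, method="marginals")
        out_ref[i], out_alt[i] = draw[:n_sites], draw[n_sites:]
    return out_ref, out_alt


def titration_curve(
    panel: TruePanel,
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    source_depth: float,
    plan: TitrationPlan,
    error_rate: float = 0.01,
    traits: tuple[str, ...] | None = None,
    het_band: tuple[float, float] = (0.8, 1.2),
) -> pd.DataFrame:
    """Closeness and concordance metrics per (depth, replicate, trait).

    Benchmark DGVs come from the panel's true genotypes; low-pass DGVs
    from posterior-mean dosages on each subsample. One row per cell; a
    cell whose downstream computation fails (e.g. degenerate variance)
    is recorded with NaN metrics and the failure reason rather than
    aborting the run.
    """
    traits = tuple(traits or panel.effects)
    effects = EffectsTable.from_panel(panel)
    truth_dgv = {t: compute_dgv(panel.genotype_matrix, effects, t) for t in traits}
    master = np.random.SeedSequence(plan.seed)
    streams = master.spawn(len(plan.target_depths) * plan.replicates)
    rows = []
    for di, depth in enumerate(plan.target_depths):
        for rep in range(plan.replicates):
            rng = np.random.default_rng(streams[di * plan.replicates + rep])
            sub_ref, sub_alt = subsample_counts(
                ref_counts, alt_counts, depth, source_depth, rng)
            _, dosages = posterior_matrix(
                sub_ref, sub_alt, panel.allele_freqs, error_rate)
            called = da_to_genotype(dosages, het_band)
            conc = concordance(called.ravel(), panel.genotype_matrix.ravel())
            het_mis = conc.class_mismatch_rate([1])
            hom_mis = conc.class_mismatch_rate([0, 2])
            for trait in traits:
                row = {"depth": depth, "replicate": rep, "trait": trait,
                       "het_mismatch": het_mis, "hom_mismatch": hom_mis,
                       "overall_mismatch": conc.mismatch_rate, "error": ""}
                try:
                    metrics = closeness(truth_dgv[trait],
                                        compute_dgv(dosages, effects, trait))
                    row.update(r_squared=metrics.r_squared, slope=metrics.slope,
                               intercept=metrics.intercept, pearson=metrics.pearson,
                               spearman=metrics.spearman)
                except ValueError as exc:   # degenerate cell: keep the run going
                    row.update(r_squared=np.nan, slope=np.nan, intercept=np.nan,
                               pearson=np.nan, spearman=np.nan, error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean and n-1 sd of each metric across replicates, per depth and trait."""
    metrics = ["r_squared", "slope", "intercept", "spearman",
               "het_mismatch", "hom_mismatch", "overall_mismatch"]
    grouped = curve.groupby(["depth", "trait"])[metrics]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
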