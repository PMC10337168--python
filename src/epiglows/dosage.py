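"""Per-site allele dosages from low-pass read counts, and concordance scoring.

Reference-panel haplotype imputation is replaced by a per-site Bayesian
posterior: a Hardy-Weinberg prior {(1-p)^2, 2p(1-p), p^2} at panel
allele frequency p, combined with a binomial read likelihood whose
alt-read probability per genotype g in {0, 1, 2} is {eps, 0.5, 1-eps}
for sequencing error rate eps. The dosage allele (DA) is the posterior
mean, a real number in [0, 2]; sites with no reads fall back to the
prior mean 2p so marker vectors stay complete. This keeps the
depth-dependent uncertainty structure of imputed dosages without
modelling linkage disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DosageRecord",
    "ConcordanceTable",
    "genotype_posterior",
    "posterior_matrix",
    "da_to_genotype",
    "concordance",
]

_CATEGORIES = ("correct", "one_allele_mismatch", "both_alleles_mismatch")


@dataclass(frozen=True)
class DosageRecord:
    """Posterior over genotypes {0,1,2} and its mean, the dosage allele."""

    posterior: tuple[float, float, float]
    dosage_allele: float


def _validate(pop_af, error_rate) -> None:
    af = np.asarray(pop_af, dtype=float)
    if np.any(af <= 0) or np.any(af >= 1):
        raise ValueError("pop_af must lie strictly inside (0, 1)")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")


def genotype_posterior(
    ref_count: int, alt_count: int, pop_af: float, error_rate: float = 0.01
) -> DosageRecord:
    """Posterior genotype distribution and dosage for one site.

    posterior(g) is proportional to HWE prior(g) times
    Binomial(alt_count | coverage, p_g) with p_g in {eps, 0.5, 1-eps}.
    With no reads the posterior equals the prior, so the dosage is the
    prior mean 2p.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be >= 0")
    post, dosage = posterior_matrix(
        np.array([[ref_count]]), np.array([[alt_count]]),
        np.array([pop_af]), error_rate)
    return DosageRecord(posterior=tuple(post[0, 0]), dosage_allele=float(dosage[0, 0]))


def posterior_matrix(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    pop_af: np.ndarray,
    error_rate: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised genotype posteriors for an (individuals x sites) count matrix.

    ``pop_af`` is a per-site vector broadcast across individuals.
    Returns (posterior with trailing genotype axis of length 3, dosage).
    Likelihoods are computed in log space; the binomial coefficient is
    common to the three genotypes and cancels.
    """
    _validate(pop_af, error_rate)
    ref = np.asarray(ref_counts)[..., None]
    alt = np.asarray(alt_counts)[..., None]
    p = np.asarray(pop_af, dtype=float)

    p_alt = np.array([max(error_rate, 1e-12), 0.5, min(1.0 - error_rate, 1.0 - 1e-12)])
    log_lik = alt * np.log(p_alt) + ref * np.log1p(-p_alt)
    log_prior = np.stack([2 * np.log1p(-p), np.log(2 * p * (1 - p)), 2 * np.log(p)],
                         axis=-1)
    log_post = log_prior + log_lik
    log_post -= log_post.max(axis=-1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=-1, keepdims=True)
    dosage = post[..., 1] + 2.0 * post[..., 2]
    return post, dosage


def da_to_genotype(dosage_allele, het_band: tuple[float, float] = (0.8, 1.2)):
    """Call genotypes from dosage alleles: het inside the inclusive band.

    1 for lo <= DA <= hi, 0 below, 2 above (defaults 0.8 and 1.2).
    Accepts a scalar or an array; values outside [0, 2] are an error.
    """
    da = np.asarray(dosage_allele, dtype=float)
    if np.any(da < 0) or np.any(da > 2):
        raise ValueError("dosage allele must lie in [0, 2]")
    lo, hi = het_band
    calls = np.where(da < lo, 0, np.where(da > hi, 2, 1))
    if np.isscalar(dosage_allele) or np.ndim(dosage_allele) == 0:
        return int(calls)
    return calls.astype(np.int8)


@dataclass(frozen=True)
class ConcordanceTable:
    """Counts of correct / one-allele / both-allele mismatches per true class.

    ``by_true_genotype`` is indexed by true genotype {0,1,2} with the
    three category columns; proportions are row-normalised.
    """

    by_true_genotype: pd.DataFrame
    mismatch_rate: float
    n_sites: int

    @property
    def proportions(self) -> pd.DataFrame:
        totals = self.by_true_genotype.sum(axis=1)
        return self.by_true_genotype.div(totals.replace(0, np.nan), axis=0)

    def class_mismatch_rate(self, true_genotypes) -> float:
        """Mismatch proportion pooled over the given true-genotype classes."""
        sub = self.by_true_genotype.loc[list(true_genotypes)]
        total = sub.values.sum()
        return float((sub["one_allele_mismatch"].sum()
                      + sub["both_alleles_mismatch"].sum()) / total) if total else np.nan


def concordance(called, true) -> ConcordanceTable:
    """Score called genotypes against array genotypes site by site.

    Category is |called - true|: 0 correct, 1 one-allele mismatch,
    2 both alleles wrong. Inputs must be aligned 1-D arrays over the
    same site set.
    """
    called = np.asarray(called).ravel()
    true = np.asarray(true).ravel()
    if called.shape != true.shape:
        raise ValueError(
            f"called ({called.shape}) and true ({true.shape}) site sets differ")
    diff = np.abs(called.astype(int) - true.astype(int))
    table = pd.DataFrame(0, index=[0, 1, 2], columns=list(_CATEGORIES))
    for g in (0, 1, 2):
        mask = true == g
        for k, cat in enumerate(_CATEGORIES):
            table.loc[g, cat] = int(np.sum(diff[mask] == k))
    return ConcordanceTable(
        by_true_genotype=table,
        mismatch_rate=float(np.mean(diff > 0)) if diff.size else np.nan,
        n_sites=int(diff.size),
    )


def dosage_frame(panel_positions, pop_af, dosages: np.ndarray) -> pd.DataFrame:
    """Dosage matrix as a tidy sites x individuals table."""
    frame = pd.DataFrame(
        dosages.T, columns=[f"ind{i:04d}" for i in range(dosages.shape[0])])
    frame.insert(0, "pos", np.asarray(panel_positions))
    frame.insert(1, "af", np.asarray(pop_af))
    return frame
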