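"""Direct genomic values and closeness between genotyping platforms.

The direct genomic value of individual i for trait t is the linear
genomic prediction

    DGV_it = mu_t + sum_j x_j * beta_jt

where x_j is the marker value (integer genotype or dosage allele in
[0, 2]), beta_jt the allele-substitution effect and mu_t a trait
intercept. Effects are fixed knowns supplied externally (from a
national evaluation in practice, from the simulator here); no effect
estimation happens in this package.

Closeness between benchmark (array-based) and low-pass DGVs is the R^2,
intercept and slope of the ordinary least-squares regression of the
benchmark on the low-pass values, plus Pearson and Spearman
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EffectsTable", "ClosenessMetrics", "compute_dgv", "closeness", "align_dosages"]


class EffectsTable:
    """Per-trait intercepts and allele-substitution effects keyed by marker.

    Markers are identified by (chrom, pos, alt). The table is a tidy
    frame with columns (trait, chrom, pos, ref, alt, beta); intercepts
    are a trait -> value mapping.
    """

    REQUIRED = ("trait", "chrom", "pos", "ref", "alt", "beta")

    def __init__(self, frame: pd.DataFrame, intercepts: dict[str, float]):
        missing = set(self.REQUIRED) - set(frame.columns)
        if missing:
            raise ValueError(f"effects table missing columns: {sorted(missing)}")
        dup = frame.duplicated(subset=["trait", "chrom", "pos", "alt"])
        if dup.any():
            raise ValueError("duplicate marker keys within a trait")
        self.frame = frame.reset_index(drop=True)
        self.intercepts = dict(intercepts)

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.frame["trait"]))

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.frame[self.frame["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not in effects table")
        return sub

    @classmethod
    def from_tsv(cls, path) -> "EffectsTable":
        """Read a tab-separated effects file.

        Intercepts are carried in header comment lines of the form
        ``#intercept <trait> <value>``.
        """
        intercepts = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#intercept"):
                _, trait, value = line.split()
                intercepts[trait] = float(value)
            elif not line.startswith("#"):
                body_start = i
                break
        frame = pd.read_csv(path, sep="\t", skiprows=body_start, dtype={"chrom": str})
        return cls(frame, intercepts)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for trait, mu in self.intercepts.items():
                fh.write(f"#intercept {trait} {mu!r}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_panel(cls, panel) -> "EffectsTable":
        """Build the table from a simulated truth panel."""
        return cls(panel.effects_frame(),
                   {t: mu for t, (mu, _) in panel.effects.items()})


def compute_dgv(
    marker_values, effects: EffectsTable, trait: str,
    marker_index: pd.Index | None = None,
) -> np.ndarray:
    """DGV per individual: ``mu_t + X @ beta_t``.

    ``marker_values`` is (individuals x markers) with columns ordered as
    the trait's effects rows, or — when ``marker_index`` (of (chrom,
    pos, alt) tuples) is given — in any order, realigned here. A marker
    present in the effects but absent from the input is an error: a
    silently zeroed marker would bias every individual's value.
    """
    sub = effects.for_trait(trait)
    x = np.atleast_2d(np.asarray(marker_values, dtype=float))
    if marker_index is not None:
        want = pd.MultiIndex.from_frame(sub[["chrom", "pos", "alt"]])
        have = pd.MultiIndex.from_tuples(list(marker_index))
        locs = have.get_indexer(want)
        if (locs < 0).any():
            missing = [tuple(m) for m in want[locs < 0][:10]]
            raise KeyError(f"markers in effects absent from input (first 10): {missing}")
        x = x[:, locs]
    if x.shape[1] != len(sub):
        raise ValueError(
            f"marker count {x.shape[1]} does not match effects rows {len(sub)}")
    if np.nanmin(x, initial=0) < 0 or np.nanmax(x, initial=0) > 2:
        raise ValueError("marker values must lie in [0, 2]")
    mu = effects.intercepts.get(trait, 0.0)
    return mu + x @ sub["beta"].to_numpy()


@dataclass(frozen=True)
class ClosenessMetrics:
    """Agreement between benchmark and low-pass DGVs.

    r_squared/intercept/slope come from OLS of the benchmark on the
    low-pass values (the benchmark is the response); Pearson and
    Spearman are symmetric.
    """

    r_squared: float
    intercept: float
    slope: float
    pearson: float
    spearman: float
    n: int


def closeness(benchmark_dgv, lps_dgv) -> ClosenessMetrics:
    """Regression and correlation agreement between two DGV vectors."""
    y = np.asarray(benchmark_dgv, dtype=float)
    x = np.asarray(lps_dgv, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("benchmark and low-pass DGVs must be equal-length vectors")
    if y.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a DGV vector: correlation undefined")
    fit = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    return ClosenessMetrics(
        r_squared=float(fit.rvalue ** 2),
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        pearson=float(fit.rvalue),
        spearman=float(rho),
        n=int(y.size),
    )


def align_dosages(
    dosages: np.ndarray,
    marker_ref: np.ndarray,
    marker_alt: np.ndarray,
    effects_ref: np.ndarray,
    effects_alt: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Orient dosages to the effects table's alt allele.

    Markers whose ref/alt are swapped relative to the effects table are
    mirrored (DA -> 2 - DA). Returns the oriented matrix and the number
    of flipped markers; markers with incompatible alleles raise.
    """
    same = (marker_ref == effects_ref) & (marker_alt == effects_alt)
    flipped = (marker_ref == effects_alt) & (marker_alt == effects_ref)
    bad = ~(same | flipped)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} markers have incompatible alleles")
    out = np.where(flipped, 2.0 - dosages, dosages)
    return out, int(flipped.sum())
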