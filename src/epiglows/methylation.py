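"""5mC methylation analysis from bedMethyl calls.

Covers the epigenetic arm of the low-pass evaluation: coverage
filtering of per-CpG calls (>= 4x, 7x, 10x), coverage-weighted mean
methylation in fixed genomic bins (500 bp default) with cross-filter
agreement, annotation of methylated sites to genomic features with the
promoter defined as TSS +/- 3,000 bp, and strand-aware density
profiles of methylated sites by distance to the nearest TSS.

bedMethyl coordinates are 0-based half-open (BED convention); GFF3
gene models (1-based, closed) are converted on load. A "methylated
site" for breakdowns and profiles is a site passing the coverage
filter with percent modified above a configurable threshold
(default 0, i.e. any modified read).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BEDMETHYL_COLUMNS",
    "FEATURE_CATEGORIES",
    "GeneModel",
    "read_bedmethyl",
    "write_bedmethyl_frame",
    "coverage_filter",
    "bin_methylation",
    "filter_agreement",
    "annotate_features",
    "feature_breakdown",
    "tss_profile",
]

BEDMETHYL_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "coverage", "percent_modified",
]

FEATURE_CATEGORIES = ("Promoter", "Exon", "Intron", "Downstream", "Distal Intergenic")


def read_bedmethyl(path) -> pd.DataFrame:
    """Read a bedMethyl (BED9+2) file into a site table."""
    frame = pd.read_csv(path, sep="\t", header=None, names=BEDMETHYL_COLUMNS,
                        dtype={"chrom": str})
    bad = ~frame["percent_modified"].between(0, 100)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} records with percent outside [0, 100]")
    return frame


def write_bedmethyl_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False,
                 columns=BEDMETHYL_COLUMNS)


def coverage_filter(sites: pd.DataFrame, min_coverage: int) -> pd.DataFrame:
    """Retain sites with coverage >= ``min_coverage`` (inclusive)."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    return sites[sites["coverage"] >= min_coverage].reset_index(drop=True)


def bin_methylation(sites: pd.DataFrame, bin_width: int = 500) -> pd.DataFrame:
    """Coverage-weighted mean percent methylation in fixed genomic bins.

    Returns one row per non-empty (chrom, bin_start) with the weighted
    mean and the contributing site count; empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if sites.empty:
        return pd.DataFrame(columns=["chrom", "bin_start", "mean_percent", "n_sites"])
    work = sites.assign(
        bin_start=(sites["start"] // bin_width) * bin_width,
        _w=sites["coverage"].astype(float),
    )
    work["_wp"] = work["_w"] * work["percent_modified"]
    grouped = work.groupby(["chrom", "bin_start"], sort=True)
    out = pd.DataFrame({
        "mean_percent": grouped["_wp"].sum() / grouped["_w"].sum(),
        "n_sites": grouped.size(),
    }).reset_index()
    return out


def filter_agreement(profile_a: pd.DataFrame, profile_b: pd.DataFrame
                     ) -> tuple[float, int]:
    """Pearson correlation of bin means over bins present in both profiles."""
    merged = profile_a.merge(profile_b, on=["chrom", "bin_start"],
                             suffixes=("_a", "_b"))
    n_shared = len(merged)
    if n_shared < 3:
        raise ValueError(f"only {n_shared} shared bins; need >= 3 for a correlation")
    r = np.corrcoef(merged["mean_percent_a"], merged["mean_percent_b"])[0, 1]
    return float(r), n_shared


@dataclass
class GeneModel:
    """Gene spans, exons and TSSs (all 0-based half-open internally).

    ``genes`` columns: gene_id, chrom, start, end, strand;
    ``exons`` columns: gene_id, chrom, start, end. The TSS is the
    strand-appropriate end of the gene span.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        bad = self.genes["end"] <= self.genes["start"]
        if bad.any():
            raise ValueError("gene spans must have end > start")

    def tss(self) -> pd.DataFrame:
        """One row per gene: chrom, position (0-based), strand."""
        pos = np.where(self.genes["strand"] == "+",
                       self.genes["start"], self.genes["end"] - 1)
        return pd.DataFrame({"chrom": self.genes["chrom"], "position": pos,
                             "strand": self.genes["strand"]})

    @classmethod
    def from_gff3(cls, path) -> "GeneModel":
        """Load genes and exons from GFF3 (1-based closed -> half-open)."""
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
        genes, exons = [], []
        for gene in db.features_of_type("gene"):
            genes.append((gene.id, gene.seqid, gene.start - 1, gene.end, gene.strand))
            for exon in db.children(gene, featuretype="exon"):
                exons.append((gene.id, exon.seqid, exon.start - 1, exon.end))
        return cls(
            genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
            exons=pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]),
        )


def _merge_intervals(starts: np.ndarray, ends: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping half-open intervals into a disjoint sorted set."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of positions in disjoint sorted half-open intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    valid = idx >= 0
    hit = np.zeros(len(pos), dtype=bool)
    hit[valid] = pos[valid] < ends[idx[valid]]
    return hit


def annotate_features(
    sites: pd.DataFrame,
    genes: GeneModel,
    promoter_window: int = 3000,
    downstream_window: int = 3000,
) -> tuple[pd.Series, int]:
    """Assign each site one genomic-feature category.

    Priority order: Promoter (within +/- ``promoter_window`` of any
    TSS) > Exon > Intron (inside a gene span, outside exons) >
    Downstream (within ``downstream_window`` past the strand-appropriate
    gene end) > Distal Intergenic. Sites on chromosomes absent from the
    model fall to Distal Intergenic; their count is returned.

    Returns (category Series aligned to ``sites``, n_unknown_chrom).
    """
    categories = pd.Series("Distal Intergenic", index=sites.index, dtype=object)
    tss = genes.tss()
    n_unknown = int((~sites["chrom"].isin(set(genes.genes["chrom"]))).sum())

    for chrom, group in sites.groupby("chrom", sort=False):
        pos = group["start"].to_numpy()
        g = genes.genes[genes.genes["chrom"] == chrom]
        if g.empty:
            continue
        e = genes.exons[genes.exons["chrom"] == chrom]
        t = tss[tss["chrom"] == chrom]

        tss_pos = np.sort(t["position"].to_numpy())
        idx = np.searchsorted(tss_pos, pos)
        dist = np.full(len(pos), np.iinfo(np.int64).max)
        for cand in (np.clip(idx - 1, 0, len(tss_pos) - 1),
                     np.clip(idx, 0, len(tss_pos) - 1)):
            dist = np.minimum(dist, np.abs(pos - tss_pos[cand]))
        in_promoter = dist <= promoter_window

        ex_s, ex_e = _merge_intervals(e["start"].to_numpy(), e["end"].to_numpy())
        in_exon = _in_intervals(pos, ex_s, ex_e)

        gn_s, gn_e = _merge_intervals(g["start"].to_numpy(), g["end"].to_numpy())
        in_gene = _in_intervals(pos, gn_s, gn_e)

        plus = g["strand"] == "+"
        ds_start = np.where(plus, g["end"], g["start"] - downstream_window)
        ds_end = np.where(plus, g["end"] + downstream_window, g["start"])
        ds_s, ds_e = _merge_intervals(ds_start.astype(np.int64), ds_end.astype(np.int64))
        in_down = _in_intervals(pos, ds_s, ds_e)

        cat = np.select(
            [in_promoter, in_exon, in_gene, in_down],
            ["Promoter", "Exon", "Intron", "Downstream"],
            default="Distal Intergenic",
        )
        categories.loc[group.index] = cat
    return categories, n_unknown


def feature_breakdown(categories: pd.Series) -> pd.Series:
    """Percentage of sites per feature category (sums to 100)."""
    if categories.empty:
        raise ValueError("no sites to break down")
    counts = categories.value_counts().reindex(FEATURE_CATEGORIES, fill_value=0)
    return 100.0 * counts / counts.sum()


def methylated_sites(sites: pd.DataFrame, min_coverage: int = 4,
                     min_percent: float = 0.0) -> pd.DataFrame:
    """Sites counted as methylated: coverage-filtered with percent > threshold."""
    kept = coverage_filter(sites, min_coverage)
    return kept[kept["percent_modified"] > min_percent].reset_index(drop=True)


def tss_profile(
    sites: pd.DataFrame,
    genes: GeneModel,
    window: int = 3000,
    profile_bin: int = 50,
) -> pd.DataFrame:
    """Density of sites by signed, strand-aware distance to the nearest TSS.

    Distance is negative upstream of the TSS (relative to gene
    orientation). Only sites within +/- ``window`` contribute; the
    returned densities sum to 1 over bins. Empty result (no site near
    any TSS) is returned as an empty frame.
    """
    if window <= 0 or profile_bin <= 0:
        raise ValueError("window and profile_bin must be positive")
    tss = genes.tss()
    distances = []
    for chrom, group in sites.groupby("chrom", sort=False):
        t = tss[tss["chrom"] == chrom]
        if t.empty:
            continue
        order = np.argsort(t["position"].to_numpy())
        tpos = t["position"].to_numpy()[order]
        tsign = np.where(t["strand"].to_numpy()[order] == "+", 1, -1)
        pos = group["start"].to_numpy()
        idx = np.searchsorted(tpos, pos)
        best = np.clip(idx - 1, 0, len(tpos) - 1)
        alt = np.clip(idx, 0, len(tpos) - 1)
        swap = np.abs(pos - tpos[alt]) < np.abs(pos - tpos[best])
        best[swap] = alt[swap]
        distances.append((pos - tpos[best]) * tsign[best])
    if not distances:
        return pd.DataFrame(columns=["bin_start", "density", "n_sites"])
    d = np.concatenate(distances)
    d = d[np.abs(d) <= window]
    if d.size == 0:
        return pd.DataFrame(columns=["bin_start", "density", "n_sites"])
    edges = np.arange(-window, window + profile_bin, profile_bin)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({
        "bin_start": edges[:-1],
        "density": counts / counts.sum(),
        "n_sites": counts,
    })
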