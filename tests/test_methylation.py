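"""Coverage filtering, binned methylation, feature annotation and TSS profiles."""

import numpy as np
import pandas as pd
import pytest

from epiglows import methylation, synthetic
from epiglows.methylation import (
    GeneModel, annotate_features, bin_methylation, coverage_filter,
    feature_breakdown, filter_agreement, read_bedmethyl, tss_profile,
)


def _sites(rows):
    """rows of (chrom, start, coverage, percent)."""
    frame = pd.DataFrame(rows, columns=["chrom", "start", "coverage",
                                        "percent_modified"])
    frame["end"] = frame["start"] + 1
    for col, val in [("name", "5mC"), ("score", 0), ("strand", "+"),
                     ("thick_start", 0), ("thick_end", 0), ("rgb", "0,0,0")]:
        frame[col] = val
    return frame[methylation.BEDMETHYL_COLUMNS]


@pytest.fixture(scope="module")
def bed_frame(methyl_truth):
    return methyl_truth.to_frame()


class TestCoverageFilter:
    def test_boundary_inclusive(self):
        sites = _sites([("1", 10, 3, 50.0), ("1", 20, 4, 50.0)])
        kept = coverage_filter(sites, 4)
        assert list(kept["start"]) == [20]

    def test_nesting_and_monotone_counts(self, bed_frame):
        kept = {t: coverage_filter(bed_frame, t) for t in (4, 7, 10)}
        s4, s7, s10 = (set(k["start"]) for k in kept.values())
        assert s10 <= s7 <= s4
        assert len(s10) < len(s7) < len(s4)


class TestBinning:
    def test_single_site_bin_mean(self):
        prof = bin_methylation(_sites([("1", 60, 5, 60.0)]))
        assert prof.iloc[0]["mean_percent"] == pytest.approx(60.0)
        assert prof.iloc[0]["bin_start"] == 0

    def test_equal_coverage_symmetry(self):
        prof = bin_methylation(_sites([("1", 10, 8, 0.0), ("1", 20, 8, 100.0)]))
        assert prof.iloc[0]["mean_percent"] == pytest.approx(50.0)

    def test_matches_bruteforce_weighted_mean(self, bed_frame):
        prof = bin_methylation(bed_frame, 500)
        # direct recomputation per bin
        for _, row in prof.sample(20, random_state=0).iterrows():
            in_bin = bed_frame[
                (bed_frame["chrom"] == row["chrom"])
                & (bed_frame["start"] // 500 * 500 == row["bin_start"])]
            expected = np.average(in_bin["percent_modified"],
                                  weights=in_bin["coverage"])
            assert row["mean_percent"] == pytest.approx(expected)
        assert prof["mean_percent"].between(0, 100).all()

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            bin_methylation(_sites([("1", 1, 1, 0.0)]), 0)


class TestAgreement:
    def test_identical_profiles_correlate_perfectly(self, bed_frame):
        prof = bin_methylation(bed_frame)
        r, n = filter_agreement(prof, prof)
        assert r == pytest.approx(1.0)
        assert n == len(prof)

    def test_anticorrelated_bins(self):
        a = pd.DataFrame({"chrom": "1", "bin_start": [0, 500, 1000],
                          "mean_percent": [0.0, 50.0, 100.0], "n_sites": 1})
        b = a.assign(mean_percent=[100.0, 50.0, 0.0])
        r, _ = filter_agreement(a, b)
        assert r == pytest.approx(-1.0)

    def test_too_few_shared_bins_flagged(self):
        a = pd.DataFrame({"chrom": "1", "bin_start": [0], "mean_percent": [1.0],
                          "n_sites": 1})
        with pytest.raises(ValueError, match="shared bins"):
            filter_agreement(a, a)

    def test_shared_truth_survives_coverage_filters(self, bed_frame):
        # same underlying levels, lambda=12 coverage: >=4x and >=10x bins agree
        p4 = bin_methylation(coverage_filter(bed_frame, 4))
        p10 = bin_methylation(coverage_filter(bed_frame, 10))
        r, n = filter_agreement(p4, p10)
        assert n >= 3
        assert r > 0.9


@pytest.fixture(scope="module")
def gene_model():
    # one + gene with two exons, one - gene far away
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB"], "chrom": ["1", "1"],
        "start": [50_000, 200_000], "end": [60_000, 210_000],
        "strand": ["+", "-"],
    })
    exons = pd.DataFrame({
        "gene_id": ["gA", "gA", "gB"], "chrom": "1",
        "start": [50_000, 58_000, 209_000], "end": [51_000, 60_000, 210_000],
    })
    return GeneModel(genes=genes, exons=exons)


def brute_force_annotation(pos, model, window=3000):
    tss = model.tss()
    if any(abs(pos - t) <= window for t in tss["position"]):
        return "Promoter"
    for _, e in model.exons.iterrows():
        if e["start"] <= pos < e["end"]:
            return "Exon"
    for _, g in model.genes.iterrows():
        if g["start"] <= pos < g["end"]:
            return "Intron"
    for _, g in model.genes.iterrows():
        if g["strand"] == "+" and g["end"] <= pos < g["end"] + window:
            return "Downstream"
        if g["strand"] == "-" and g["start"] - window <= pos < g["start"]:
            return "Downstream"
    return "Distal Intergenic"


class TestAnnotation:
    @pytest.mark.parametrize("pos,expected", [
        (50_000, "Promoter"),            # exactly at the + TSS
        (46_999, "Distal Intergenic"),   # 3,001 bp upstream: outside the window
        (47_000, "Promoter"),            # exactly at the window edge
        (58_500, "Exon"),                # exon > intron even far from TSS
        (55_000, "Intron"),
        (61_000, "Downstream"),          # past the + gene end
        (209_999, "Promoter"),           # - strand TSS at the gene's high end
        (150_000, "Distal Intergenic"),
    ])
    def test_category_boundaries(self, gene_model, pos, expected):
        sites = _sites([("1", pos, 5, 50.0)])
        cats, _ = annotate_features(sites, gene_model)
        assert cats.iloc[0] == expected

    def test_matches_bruteforce_scan(self, gene_model):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(300_000, size=2000, replace=False))
        sites = _sites([("1", int(p), 5, 50.0) for p in pos])
        cats, _ = annotate_features(sites, gene_model)
        for p, got in zip(pos, cats):
            assert got == brute_force_annotation(int(p), gene_model), p

    def test_unknown_chromosome_counts_as_distal(self, gene_model):
        sites = _sites([("chrUn", 5, 5, 50.0)])
        cats, n_unknown = annotate_features(sites, gene_model)
        assert cats.iloc[0] == "Distal Intergenic"
        assert n_unknown == 1

    def test_breakdown_sums_to_100(self, gene_model):
        rng = np.random.default_rng(10)
        sites = _sites([("1", int(p), 5, 50.0)
                        for p in rng.choice(300_000, 500, replace=False)])
        cats, _ = annotate_features(sites, gene_model)
        pct = feature_breakdown(cats)
        assert pct.sum() == pytest.approx(100.0, abs=0.01)
        assert list(pct.index) == list(methylation.FEATURE_CATEGORIES)


class TestGff:
    def test_gff3_load_converts_coordinates(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "1\tsrc\texon\t101\t150\t.\t+\t.\tID=g1.e1;Parent=g1\n"
            "1\tsrc\tgene\t501\t600\t.\t-\t.\tID=g2\n"
            "1\tsrc\texon\t551\t600\t.\t-\t.\tID=g2.e1;Parent=g2\n")
        model = GeneModel.from_gff3(gff)
        g1 = model.genes[model.genes["gene_id"] == "g1"].iloc[0]
        assert (g1["start"], g1["end"]) == (100, 200)   # half-open
        tss = model.tss().set_index(model.genes["gene_id"])
        assert tss.loc["g1", "position"] == 100
        assert tss.loc["g2", "position"] == 599         # - strand: high end


class TestTssProfile:
    def test_all_sites_at_tss_concentrate_centrally(self, gene_model):
        sites = _sites([("1", 50_000, 5, 50.0)] * 10)
        prof = tss_profile(sites, gene_model, window=3000, profile_bin=50)
        assert prof["density"].sum() == pytest.approx(1.0)
        top = prof.loc[prof["density"].idxmax(), "bin_start"]
        assert top == 0  # distance zero falls in the [0, 50) bin

    def test_density_normalised(self, gene_model):
        rng = np.random.default_rng(11)
        sites = _sites([("1", int(p), 5, 50.0)
                        for p in rng.integers(47_000, 53_000, 300)])
        prof = tss_profile(sites, gene_model)
        assert prof["density"].sum() == pytest.approx(1.0)

    def test_strand_aware_sign(self, gene_model):
        # 100 bp before the - strand TSS along the genome = downstream (+100)
        sites = _sites([("1", 209_999 - 100, 5, 50.0)])
        prof = tss_profile(sites, gene_model)
        occupied = prof[prof["n_sites"] > 0]
        assert len(occupied) == 1
        assert occupied.iloc[0]["bin_start"] == 100

    def test_no_sites_near_tss_gives_empty_profile(self, gene_model):
        prof = tss_profile(_sites([("1", 150_000, 5, 50.0)]), gene_model)
        assert prof.empty


class TestBedmethylIO:
    def test_roundtrip(self, tmp_path, methyl_truth):
        path = tmp_path / "m.bed"
        synthetic.write_bedmethyl(methyl_truth, str(path))
        sites = read_bedmethyl(path)
        frame = methyl_truth.to_frame()
        assert len(sites) == len(frame)
        assert np.array_equal(sites["start"], frame["start"])
        assert np.array_equal(sites["coverage"], frame["coverage"])
        assert np.allclose(sites["percent_modified"], frame["percent_modified"],
                           atol=0.005)

    def test_bad_percent_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        _sites([("1", 1, 5, 150.0)]).to_csv(path, sep="\t", header=False,
                                            index=False)
        with pytest.raises(ValueError):
            read_bedmethyl(path)
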