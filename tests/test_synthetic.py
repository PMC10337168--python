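"""Generator checks: distributions match their stated models, truth is consistent."""

import numpy as np
import pytest
from scipy import stats

from epiglows import synthetic
from epiglows.synthetic import (
    ConfigError, MethylConfig, PopulationConfig, ReadSimConfig,
    simulate_methylation, simulate_panel, simulate_pileups, simulate_sam_reads,
)


class TestPanel:
    def test_degenerate_maf_range_pins_frequencies(self):
        panel = simulate_panel(PopulationConfig(n_snps=10, maf_range=(0.5, 0.5), seed=0))
        assert np.allclose(panel.allele_freqs, 0.5)

    def test_same_seed_gives_identical_panels(self):
        cfg = PopulationConfig(n_individuals=30, n_snps=40, seed=42)
        a, b = simulate_panel(cfg), simulate_panel(cfg)
        assert np.array_equal(a.genotype_matrix, b.genotype_matrix)
        assert np.array_equal(a.positions, b.positions)
        for t in a.effects:
            assert a.effects[t][0] == b.effects[t][0]
            assert np.array_equal(a.effects[t][1], b.effects[t][1])

    def test_hwe_genotype_proportions_at_half(self):
        # Binomial(2, 0.5) oracle: proportions (0.25, 0.5, 0.25) within 3 SE
        panel = simulate_panel(PopulationConfig(
            n_individuals=10_000, n_snps=1, maf_range=(0.5, 0.5), seed=3))
        g = panel.genotype_matrix[:, 0]
        for k, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            se = np.sqrt(expected * (1 - expected) / 10_000)
            assert abs(np.mean(g == k) - expected) < 3 * se

    def test_invariants(self, small_panel):
        assert set(np.unique(small_panel.genotype_matrix)) <= {0, 1, 2}
        assert np.all(np.diff(small_panel.positions) > 0)
        assert np.all((small_panel.allele_freqs > 0) & (small_panel.allele_freqs < 1))
        assert np.all(small_panel.ref != small_panel.alt)

    @pytest.mark.parametrize("kwargs", [
        {"maf_range": (0.0, 0.5)}, {"maf_range": (0.4, 0.2)},
        {"maf_range": (0.1, 0.6)}, {"n_individuals": 0}, {"n_snps": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            PopulationConfig(**kwargs)


class TestPileups:
    def test_no_error_hom_ref_never_shows_alt(self):
        panel = simulate_panel(PopulationConfig(
            n_individuals=50, n_snps=50, maf_range=(0.05, 0.05), seed=1))
        panel.genotype_matrix[:] = 0
        _, alt = simulate_pileups(panel, ReadSimConfig(base_error_rate=0.0, seed=1))
        assert alt.sum() == 0

    def test_poisson_mean_coverage(self, small_panel):
        # 10,000+ site-individual draws; mean within 3 SE of lambda
        panel = simulate_panel(PopulationConfig(n_individuals=100, n_snps=100, seed=2))
        ref, alt = simulate_pileups(panel, ReadSimConfig(target_depth=2.0, seed=2))
        cov = ref + alt
        se = np.sqrt(2.0 / cov.size)
        assert abs(cov.mean() - 2.0) < 3 * se

    def test_het_alt_fraction_converges_to_half(self):
        panel = simulate_panel(PopulationConfig(n_individuals=1, n_snps=200, seed=4))
        panel.genotype_matrix[:] = 1
        ref, alt = simulate_pileups(
            panel, ReadSimConfig(target_depth=500.0, base_error_rate=0.0, seed=4))
        frac = alt.sum() / (ref + alt).sum()
        n = (ref + alt).sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


class TestSamReads:
    def test_clean_reads_have_zero_nm_single_match_op(self, reference_sequence):
        cfg = ReadSimConfig(base_error_rate=0.0, indel_rate=0.0, seed=9)
        reads = simulate_sam_reads(reference_sequence, cfg, 20)
        for r in reads:
            assert r.nm == 0
            assert r.cigar == [(0, len(r.sequence))]

    def test_nm_matches_independent_edit_recount(self, simulated_reads, reference_sequence):
        # brute-force base-by-base recount of the alignment each read encodes
        for read in simulated_reads:
            subs = indels = 0
            qpos, rpos = 0, read.start
            for op, ln in read.cigar:
                if op == 0:     # M: compare bases
                    for k in range(ln):
                        if read.sequence[qpos + k] != reference_sequence[rpos + k]:
                            subs += 1
                    qpos += ln
                    rpos += ln
                elif op == 1:   # I
                    indels += ln
                    qpos += ln
                elif op == 2:   # D
                    indels += ln
                    rpos += ln
            assert subs + indels == read.nm
            assert subs == read.true_substitutions

    def test_cigar_query_lengths_sum_to_sequence_length(self, simulated_reads):
        for r in simulated_reads:
            q = sum(ln for op, ln in r.cigar if op in (0, 1, 4))
            assert q == len(r.sequence)

    def test_short_reference_rejected(self):
        with pytest.raises(ConfigError):
            simulate_sam_reads("ACGT", ReadSimConfig(read_length_min=200), 1)

    def test_sam_roundtrip_byte_identical_for_same_seed(self, tmp_path, reference_sequence):
        cfg = ReadSimConfig(base_error_rate=0.01, seed=21)
        for name in ("a.sam", "b.sam"):
            reads = simulate_sam_reads(reference_sequence, cfg, 30)
            synthetic.write_sam(reads, str(tmp_path / name), len(reference_sequence))
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()


class TestMethylation:
    def test_fully_methylated_sites_report_100_percent(self):
        truth = simulate_methylation(MethylConfig(
            n_sites=200, hyper_fraction=1.0, hyper_beta=(1e6, 1e-3), seed=5))
        frame = truth.to_frame()
        assert np.allclose(frame["percent_modified"], 100.0)

    def test_modified_counts_bounded_by_coverage(self, methyl_truth):
        assert np.all(methyl_truth.modified <= methyl_truth.coverage)
        assert np.all((methyl_truth.levels >= 0) & (methyl_truth.levels <= 1))

    def test_binomial_support_at_known_level(self):
        # one site, huge coverage: percent within 3 SE of 50
        truth = simulate_methylation(MethylConfig(
            n_sites=1, mean_coverage=10_000,
            hyper_fraction=1.0, hyper_beta=(1e7, 1e7), seed=6))  # level ~= 0.5
        pct = 100 * truth.modified[0] / truth.coverage[0]
        se = 100 * np.sqrt(0.25 / truth.coverage[0])
        assert abs(pct - 50) < 3 * se + 1e-6

    def test_coverage_tail_matches_poisson(self):
        truth = simulate_methylation(MethylConfig(
            n_sites=20_000, genome_length=10_000_000, mean_coverage=2.0, seed=8))
        frac = np.mean(truth.coverage >= 4)
        expected = stats.poisson.sf(3, 2.0)
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(frac - expected) < 3 * se

    def test_bedmethyl_deterministic_given_seed(self, tmp_path):
        cfg = MethylConfig(n_sites=500, seed=17)
        for name in ("a.bed", "b.bed"):
            synthetic.write_bedmethyl(simulate_methylation(cfg), str(tmp_path / name))
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()
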