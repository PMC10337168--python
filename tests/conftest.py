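import numpy as np
import pytest

from epiglows import synthetic


@pytest.fixture(scope="session")
def small_panel():
    """20 individuals x 60 sites, fixed seed."""
    return synthetic.simulate_panel(synthetic.PopulationConfig(
        n_individuals=20, n_snps=60, genome_length=1_000_000, seed=11))


@pytest.fixture(scope="session")
def reference_sequence():
    rng = np.random.default_rng(5)
    return "".join(rng.choice(list("ACGT"), size=30_000))


@pytest.fixture(scope="session")
def simulated_reads(reference_sequence):
    """Reads with substitutions and indels, truth retained per read."""
    cfg = synthetic.ReadSimConfig(
        target_depth=2.0, base_error_rate=0.02, indel_rate=0.002,
        read_length_mean=2000, read_length_sd=600, read_length_min=300, seed=7)
    return synthetic.simulate_sam_reads(reference_sequence, cfg, 200)


@pytest.fixture()
def sam_path(tmp_path, simulated_reads, reference_sequence):
    path = tmp_path / "reads.sam"
    synthetic.write_sam(simulated_reads, str(path), len(reference_sequence))
    return path


@pytest.fixture(scope="session")
def methyl_truth():
    return synthetic.simulate_methylation(synthetic.MethylConfig(
        n_sites=5000, genome_length=2_000_000, mean_coverage=12.0, seed=13))
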