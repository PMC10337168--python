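"""Synthetic data with known truth for the low-pass sequencing pipeline.

Everything the downstream stages consume can be generated here: a marker
panel with Hardy-Weinberg genotypes and per-trait allele-substitution
effects, per-site read pileups with a uniform base-error rate, aligned
long reads as SAM records with consistent CIGAR/NM, and per-CpG 5mC
methylation calls in bedMethyl form.

Sites are simulated independently (no linkage disequilibrium): the
dosage-calibration and DGV-closeness analyses only require marginal
per-site behaviour. A single global seed is expanded into per-stage
substreams via :class:`numpy.random.SeedSequence` so each stage can be
regenerated independently and deterministically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "PopulationConfig",
    "TruePanel",
    "ReadSimConfig",
    "SimulatedRead",
    "MethylConfig",
    "MethylTruth",
    "simulate_panel",
    "simulate_pileups",
    "simulate_sam_reads",
    "write_sam",
    "simulate_methylation",
    "write_bedmethyl",
]

DEFAULT_TRAITS = ("MY", "FY", "PY")


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PopulationConfig:
    """Marker-panel simulation parameters.

    maf_range bounds the uniform distribution of alternate-allele
    frequencies; genome_length bounds marker coordinates (bp).
    """

    n_individuals: int = 200
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    genome_length: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ConfigError("n_individuals and n_snps must be >= 1")
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.genome_length < self.n_snps:
            raise ConfigError("genome_length must accommodate n_snps distinct positions")


@dataclass
class TruePanel:
    """Ground-truth marker panel: sites, frequencies, genotypes and effects.

    genotype_matrix is individuals x sites with entries in {0, 1, 2}
    (alternate-allele counts). effects maps trait id -> (intercept,
    per-site effect vector).
    """

    chrom: str
    positions: np.ndarray          # 1-based, strictly increasing
    ref: np.ndarray                # nucleotide per site
    alt: np.ndarray
    allele_freqs: np.ndarray       # alt-allele frequency in (0, 1)
    genotype_matrix: np.ndarray    # (n_individuals, n_snps) int8
    effects: dict[str, tuple[float, np.ndarray]] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.genotype_matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotype_matrix.shape[1]

    def effects_frame(self) -> pd.DataFrame:
        """Effects as a tidy table (trait, chrom, pos, ref, alt, beta)."""
        frames = []
        for trait, (_, beta) in self.effects.items():
            frames.append(pd.DataFrame({
                "trait": trait, "chrom": self.chrom, "pos": self.positions,
                "ref": self.ref, "alt": self.alt, "beta": beta,
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters.

    target_depth is the mean fold-coverage lambda (Poisson per site);
    base_error_rate is the per-base substitution probability epsilon;
    indel_rate is insertion/deletion events per base (each kind).
    """

    target_depth: float = 2.0
    base_error_rate: float = 0.01
    read_length_mean: float = 5000.0
    read_length_sd: float = 1500.0
    read_length_min: int = 200
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ConfigError("target_depth must be > 0")
        if not (0 <= self.base_error_rate < 0.5):
            raise ConfigError("base_error_rate must be in [0, 0.5)")
        if self.read_length_min < 1:
            raise ConfigError("read_length_min must be >= 1")
        if self.indel_rate < 0:
            raise ConfigError("indel_rate must be >= 0")


def _substream(seed: int, stage: int) -> np.random.Generator:
    """Independent generator for a pipeline stage derived from one seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


_BASES = np.array(list("ACGT"))


def simulate_panel(
    config: PopulationConfig,
    traits: tuple[str, ...] = DEFAULT_TRAITS,
    effect_sd: float = 1.0,
    intercept_sd: float = 1.0,
) -> TruePanel:
    """Simulate a marker panel under Hardy-Weinberg equilibrium.

    Allele frequencies are Uniform(maf_range); genotypes per site are
    Binomial(2, p) draws (HWE, no LD); per-trait allele-substitution
    effects are zero-mean normal with sd ``effect_sd``. Deterministic
    given ``config.seed``.
    """
    rng = _substream(config.seed, 0)
    positions = np.sort(rng.choice(config.genome_length, size=config.n_snps, replace=False)) + 1
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    genotypes = rng.binomial(2, freqs, size=(config.n_individuals, config.n_snps)).astype(np.int8)
    ref_idx = rng.integers(0, 4, size=config.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_snps)) % 4
    effects = {}
    for trait in traits:
        mu = float(rng.normal(0.0, intercept_sd))
        beta = rng.normal(0.0, effect_sd, size=config.n_snps)
        effects[trait] = (mu, beta)
    return TruePanel(
        chrom="1",
        positions=positions,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        allele_freqs=freqs,
        genotype_matrix=genotypes,
        effects=effects,
    )


def simulate_pileups(
    panel: TruePanel, readsim: ReadSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-site read counts (ref_count, alt_count) per individual.

    Coverage at each (individual, site) is Poisson(target_depth). Each
    read reports the true allele with probability 1 - epsilon and the
    other allele with probability epsilon; for heterozygotes both
    alleles are equally likely to be sampled, so the alt-read
    probability per genotype g in {0, 1, 2} is {eps, 0.5, 1 - eps}.

    Returns (ref_counts, alt_counts), each (n_individuals, n_snps).
    """
    rng = _substream(readsim.seed, 1)
    shape = panel.genotype_matrix.shape
    coverage = rng.poisson(readsim.target_depth, size=shape)
    p_alt = _alt_read_probability(panel.genotype_matrix, readsim.base_error_rate)
    alt_counts = rng.binomial(coverage, p_alt)
    return coverage - alt_counts, alt_counts


def _alt_read_probability(genotypes: np.ndarray, error_rate: float) -> np.ndarray:
    lookup = np.array([error_rate, 0.5, 1.0 - error_rate])
    return lookup[genotypes]


@dataclass
class SimulatedRead:
    """One simulated aligned read plus the ground truth injected into it."""

    name: str
    start: int                 # 0-based reference start
    sequence: str
    cigar: list[tuple[int, int]]   # pysam op tuples
    nm: int
    mean_quality: float
    true_substitutions: int
    true_insertion_bases: int
    true_deletion_bases: int


# pysam CIGAR operation codes
_M, _I, _D = 0, 1, 2


def simulate_sam_reads(
    reference: str,
    readsim: ReadSimConfig,
    n_reads: int,
    mean_quality: float = 20.0,
) -> list[SimulatedRead]:
    """Simulate aligned reads with consistent CIGAR and NM tags.

    Reads are windows of ``reference`` with substitutions injected at
    ``base_error_rate`` per base and insertions/deletions each at
    ``indel_rate`` events per base (geometric length, mean 2). The
    emitted NM equals substitutions + inserted bases + deleted bases
    actually introduced, and the per-read truth is retained so tests
    can recount edits independently.
    """
    rng = _substream(readsim.seed, 2)
    ref_len = len(reference)
    if ref_len < readsim.read_length_min:
        raise ConfigError("reference shorter than the minimum read length")
    reads = []
    for i in range(n_reads):
        length = int(rng.normal(readsim.read_length_mean, readsim.read_length_sd))
        length = max(readsim.read_length_min, min(length, ref_len))
        start = int(rng.integers(0, ref_len - length + 1))
        read = _mutate_window(reference, start, length, readsim, rng, name=f"read{i:05d}")
        read.mean_quality = float(mean_quality)
        reads.append(read)
    return reads


def _mutate_window(
    reference: str, start: int, length: int,
    readsim: ReadSimConfig, rng: np.random.Generator, name: str,
) -> SimulatedRead:
    seq: list[str] = []
    cigar: list[tuple[int, int]] = []
    n_sub = ins_bases = del_bases = 0

    def push(op: int, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    pos = start
    end = start + length
    while pos < end:
        u = rng.random()
        if u < readsim.indel_rate:
            ln = min(int(rng.geometric(0.5)), end - pos)
            seq.extend(rng.choice(_BASES, size=ln))
            push(_I, ln)
            ins_bases += ln
        elif u < 2 * readsim.indel_rate:
            ln = min(int(rng.geometric(0.5)), end - pos)
            push(_D, ln)
            del_bases += ln
            pos += ln
            continue
        base = reference[pos]
        if rng.random() < readsim.base_error_rate:
            base = str(rng.choice(_BASES[_BASES != base]))
            n_sub += 1
        seq.append(base)
        push(_M, 1)
        pos += 1

    # a CIGAR must not end in a deletion; drop one if the window ended mid-event
    if cigar and cigar[-1][0] == _D:
        del_bases -= cigar[-1][1]
        cigar.pop()

    return SimulatedRead(
        name=name,
        start=start,
        sequence="".join(seq),
        cigar=cigar,
        nm=n_sub + ins_bases + del_bases,
        mean_quality=20.0,
        true_substitutions=n_sub,
        true_insertion_bases=ins_bases,
        true_deletion_bases=del_bases,
    )


def write_sam(reads: list[SimulatedRead], path: str, reference_length: int,
              reference_name: str = "ref") -> None:
    """Write simulated reads as a SAM file with NM:i tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference_name, "LN": int(reference_length)}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.name
            seg.query_sequence = read.sequence
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = read.start
            seg.mapping_quality = 60
            seg.cigartuples = read.cigar
            seg.query_qualities = pysam.qualitystring_to_array(
                chr(int(round(read.mean_quality)) + 33) * len(read.sequence))
            seg.set_tag("NM", read.nm, "i")
            out.write(seg)


@dataclass(frozen=True)
class MethylConfig:
    """Per-CpG 5mC simulation parameters.

    True methylation levels come from a two-component Beta mixture
    (hypomethylated vs hypermethylated CpGs); coverage is Poisson(lambda)
    and the modified-read count Binomial(coverage, level).
    """

    n_sites: int = 10_000
    genome_length: int = 10_000_000
    mean_coverage: float = 12.0
    hyper_fraction: float = 0.7
    hypo_beta: tuple[float, float] = (0.5, 10.0)
    hyper_beta: tuple[float, float] = (10.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.mean_coverage <= 0:
            raise ConfigError("n_sites >= 1 and mean_coverage > 0 required")
        if not (0 <= self.hyper_fraction <= 1):
            raise ConfigError("hyper_fraction must be in [0, 1]")


@dataclass
class MethylTruth:
    """Ground-truth 5mC sites: positions, levels, coverage, modified counts."""

    chrom: str
    positions: np.ndarray      # 0-based CpG starts
    levels: np.ndarray         # true methylation fraction in [0, 1]
    coverage: np.ndarray
    modified: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """bedMethyl-style table; zero-coverage sites are omitted."""
        keep = self.coverage > 0
        pct = np.zeros(len(self.positions))
        pct[keep] = 100.0 * self.modified[keep] / self.coverage[keep]
        return pd.DataFrame({
            "chrom": self.chrom,
            "start": self.positions[keep],
            "end": self.positions[keep] + 1,
            "name": "5mC",
            "score": np.minimum(self.coverage[keep], 1000),
            "strand": "+",
            "thick_start": self.positions[keep],
            "thick_end": self.positions[keep] + 1,
            "rgb": "0,0,0",
            "coverage": self.coverage[keep],
            "percent_modified": pct[keep],
        })


def simulate_methylation(config: MethylConfig) -> MethylTruth:
    """Simulate per-CpG methylation with binomial read support."""
    rng = _substream(config.seed, 3)
    positions = np.sort(rng.choice(config.genome_length, size=config.n_sites, replace=False))
    is_hyper = rng.random(config.n_sites) < config.hyper_fraction
    levels = np.where(
        is_hyper,
        rng.beta(*config.hyper_beta, size=config.n_sites),
        rng.beta(*config.hypo_beta, size=config.n_sites),
    )
    coverage = rng.poisson(config.mean_coverage, size=config.n_sites)
    modified = rng.binomial(coverage, levels)
    return MethylTruth(chrom="1", positions=positions, levels=levels,
                       coverage=coverage, modified=modified)


def write_bedmethyl(truth: MethylTruth, path: str) -> None:
    """Write a bedMethyl (BED9+2) file: coverage and percent-modified columns."""
    frame = truth.to_frame().copy()
    frame["percent_modified"] = frame["percent_modified"].map(lambda v: f"{v:.2f}")
    frame.to_csv(path, sep="\t", header=False, index=False)
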