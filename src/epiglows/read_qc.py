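"""Read filtering, per-read basecalling accuracy and coverage summaries.

Per-read accuracy is derived from the alignment edit distance: the NM
tag counts single-base mismatches plus inserted plus deleted bases, so
the single-nucleotide total mismatch score is

    TMS = NM - (length of insertions) - (length of deletions)

and per-read accuracy is ``1 - TMS / read_length``. Read length is the
full query sequence length by default (soft clips included); aligned
length is available via a flag since aligner conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

__all__ = [
    "AlignedRead",
    "ReadFilterResult",
    "AccuracySummary",
    "CoverageSummary",
    "filter_reads",
    "compute_tms",
    "read_accuracy",
    "reads_from_sam",
    "accuracy_table",
    "summarize_accuracy",
    "coverage_stats",
]


@dataclass(frozen=True)
class AlignedRead:
    """Minimal view of one mapped read for accuracy scoring."""

    name: str
    query_length: int
    nm_tag: int | None
    insertion_length_total: int
    deletion_length_total: int
    aligned_length: int
    mean_quality: float | None
    mapped: bool = True

    @classmethod
    def from_segment(cls, seg: pysam.AlignedSegment) -> "AlignedRead":
        nm = seg.get_tag("NM") if seg.has_tag("NM") else None
        ins = dels = aligned = 0
        for op, ln in seg.cigartuples or []:
            if op == 1:
                ins += ln
            elif op == 2:
                dels += ln
            elif op in (0, 7, 8):
                aligned += ln
        quals = seg.query_qualities
        mean_q = float(np.mean(quals)) if quals is not None and len(quals) else None
        return cls(
            name=seg.query_name,
            query_length=seg.query_length or seg.infer_read_length() or 0,
            nm_tag=int(nm) if nm is not None else None,
            insertion_length_total=ins,
            deletion_length_total=dels,
            aligned_length=aligned,
            mean_quality=mean_q,
            mapped=not seg.is_unmapped,
        )


@dataclass
class ReadFilterResult:
    """Retained reads plus per-reason discard counts."""

    retained: list = field(default_factory=list)
    n_short: int = 0
    n_low_quality: int = 0
    n_missing_quality: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_short + self.n_low_quality + self.n_missing_quality


def filter_reads(reads, min_length_bp: int = 150, min_quality: float = 10.0,
                 length=None, quality=None) -> ReadFilterResult:
    """Discard reads with length <= ``min_length_bp`` or quality < ``min_quality``.

    Both boundaries follow the QC rule for nanopore reads: a read of
    exactly 150 bp is discarded, a read at quality exactly 10 is kept.
    ``length`` and ``quality`` are optional accessors for foreign read
    objects; by default attributes ``query_length`` / ``mean_quality``
    are used. A read with no quality value fails the quality rule and
    is counted separately.
    """
    length = length or (lambda r: r.query_length)
    quality = quality or (lambda r: r.mean_quality)
    result = ReadFilterResult()
    for read in reads:
        if length(read) <= min_length_bp:
            result.n_short += 1
            continue
        q = quality(read)
        if q is None:
            result.n_missing_quality += 1
        elif q < min_quality:
            result.n_low_quality += 1
        else:
            result.retained.append(read)
    return result


def compute_tms(read: AlignedRead) -> int | None:
    """Single-nucleotide mismatch count: NM minus total indel length.

    Clamped at zero because NM conventions vary across aligners; a
    negative value indicates tag dialect, not negative error. Returns
    None (caller should skip and count) when the NM tag is absent.
    """
    if read.nm_tag is None:
        return None
    return max(0, read.nm_tag - read.insertion_length_total - read.deletion_length_total)


def read_accuracy(tms: int, read_length: int) -> float:
    """Per-read accuracy ``1 - TMS / read_length``."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if tms < 0:
        raise ValueError("tms must be >= 0")
    if tms > read_length:
        raise ValueError(
            f"TMS ({tms}) exceeds read length ({read_length}): inconsistent alignment")
    return 1.0 - tms / read_length


def reads_from_sam(path: str) -> list[AlignedRead]:
    """Load primary mapped alignments; secondary/supplementary are excluded."""
    reads = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            reads.append(AlignedRead.from_segment(seg))
    return reads


def accuracy_table(reads, use_aligned_length: bool = False):
    """Per-read (name, tms, length, accuracy) rows; reads without NM are skipped.

    Returns (rows, n_skipped). ``use_aligned_length`` switches the
    denominator of the accuracy formula from query length to aligned
    reference-consuming length.
    """
    rows = []
    n_skipped = 0
    for read in reads:
        tms = compute_tms(read)
        if tms is None:
            n_skipped += 1
            continue
        length = read.aligned_length if use_aligned_length else read.query_length
        rows.append((read.name, tms, length, read_accuracy(tms, length)))
    return rows, n_skipped


@dataclass(frozen=True)
class AccuracySummary:
    median: float
    mode: float
    n_reads: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray


def summarize_accuracy(accuracies, bin_width: float = 0.001) -> AccuracySummary:
    """Median and histogram-mode of per-read accuracies.

    The mode is the midpoint of the highest-count bin on a fixed grid
    of width ``bin_width`` over [0, 1]; ties break toward the
    higher-accuracy bin, which keeps the estimate reproducible without
    a bandwidth choice.
    """
    acc = np.asarray(list(accuracies), dtype=float)
    if acc.size == 0:
        raise ValueError("summarize_accuracy requires at least one read")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(np.clip(acc, 0.0, 1.0), bins=edges)
    best = np.flatnonzero(counts == counts.max())[-1]   # tie -> higher accuracy
    mode = float((edges[best] + edges[best + 1]) / 2)
    return AccuracySummary(
        median=float(np.median(acc)),
        mode=min(mode, 1.0),
        n_reads=int(acc.size),
        bin_edges=edges,
        bin_counts=counts,
    )


@dataclass(frozen=True)
class CoverageSummary:
    """Mean fold-depth and breadth (% reference positions covered >= 1x)."""

    mean_depth: float
    breadth: float


def coverage_stats(intervals, reference_length: int) -> CoverageSummary:
    """Depth and breadth from aligned reference intervals (0-based half-open).

    mean_depth = total aligned reference bases / reference length;
    breadth = percent of positions with at least one aligned base.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    delta = np.zeros(reference_length + 1, dtype=np.int64)
    total = 0
    for start, end in intervals:
        if start < 0 or end > reference_length or start > end:
            raise ValueError(f"interval ({start}, {end}) outside reference")
        delta[start] += 1
        delta[end] -= 1
        total += end - start
    depth_profile = np.cumsum(delta[:-1])
    return CoverageSummary(
        mean_depth=total / reference_length,
        breadth=100.0 * np.count_nonzero(depth_profile) / reference_length,
    )


def sam_coverage(path: str, reference_length: int) -> CoverageSummary:
    """Coverage summary over primary alignments in a SAM/BAM file."""
    intervals = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            intervals.append((seg.reference_start, seg.reference_end))
    return coverage_stats(intervals, reference_length)
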