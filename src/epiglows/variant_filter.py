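"""Post-calling variant filters for low-pass sequencing.

Two rules are applied to raw low-pass variant calls before imputation:

* depth rescue — calls at sequencing depth <= 2 are discarded unless
  the called alternate allele matches a reference-panel variant at the
  same position (low-depth calls corroborated by the panel are kept);
* allele-fraction zygosity — a site is heterozygous when the alt-read
  fraction is strictly between 0 and 0.90, homozygous-alt at >= 0.90,
  homozygous-ref at exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

__all__ = [
    "VariantCall",
    "PanelIndex",
    "FilterCounts",
    "depth_rescue_filter",
    "call_zygosity",
    "read_vcf",
    "write_vcf",
]

HOM_REF, HET, HOM_ALT, UNASSIGNED = "hom_ref", "het", "hom_alt", "unassigned"


@dataclass(frozen=True)
class VariantCall:
    """One bi-allelic variant call (multi-allelic records are split upstream)."""

    chrom: str
    pos: int                     # 1-based
    ref: str
    alt: str
    depth: int | None
    alt_fraction: float | None
    genotype_class: str = UNASSIGNED

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


class PanelIndex:
    """Reference-panel variant lookup keyed by (chrom, pos, alt allele)."""

    def __init__(self, keys=()):
        self._keys = set(keys)

    def __contains__(self, key) -> bool:
        return tuple(key) in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanelIndex":
        """Load a 3-column (chrom, pos, alt) tab-separated panel."""
        frame = pd.read_csv(path, sep="\t", header=None,
                            names=["chrom", "pos", "alt"], dtype={"chrom": str})
        return cls(zip(frame["chrom"], frame["pos"].astype(int), frame["alt"]))

    @classmethod
    def from_vcf(cls, path: str | Path) -> "PanelIndex":
        keys = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    keys.append((rec.chrom, rec.pos, alt))
        return cls(keys)


@dataclass
class FilterCounts:
    """Partition of the input calls by filter outcome."""

    retained_depth: int = 0       # depth above the discard threshold
    rescued_panel: int = 0        # low depth but corroborated by the panel
    discarded_low_depth: int = 0
    discarded_missing_depth: int = 0

    @property
    def n_retained(self) -> int:
        return self.retained_depth + self.rescued_panel

    @property
    def n_input(self) -> int:
        return self.n_retained + self.discarded_low_depth + self.discarded_missing_depth


def depth_rescue_filter(
    calls, panel: PanelIndex, max_discard_depth: int = 2
) -> tuple[list[VariantCall], FilterCounts]:
    """Discard low-depth calls unless the panel carries the same alt allele.

    A call is retained iff depth > ``max_discard_depth``, or depth is at
    or below it but (chrom, pos, alt) is present in the reference panel.
    Calls with no depth value are discarded and counted separately.
    """
    retained: list[VariantCall] = []
    counts = FilterCounts()
    for call in calls:
        if call.depth is None:
            counts.discarded_missing_depth += 1
        elif call.depth > max_discard_depth:
            counts.retained_depth += 1
            retained.append(call)
        elif call.key in panel:
            counts.rescued_panel += 1
            retained.append(call)
        else:
            counts.discarded_low_depth += 1
    return retained, counts


def call_zygosity(call: VariantCall, het_max: float = 0.90) -> VariantCall:
    """Assign a genotype class from the within-sample alt-read fraction.

    het for 0 < AF < ``het_max``; hom_alt for AF >= ``het_max``; hom_ref
    for AF exactly 0. Both boundaries are exclusive for the het class.
    """
    af = call.alt_fraction
    if af is None or not (0.0 <= af <= 1.0):
        raise ValueError(f"alt_fraction must be in [0, 1], got {af!r}")
    if af == 0.0:
        cls = HOM_REF
    elif af < het_max:
        cls = HET
    else:
        cls = HOM_ALT
    return replace(call, genotype_class=cls)


_GT = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), UNASSIGNED: (None, None)}
_GT_INV = {(0, 0): HOM_REF, (0, 1): HET, (1, 0): HET, (1, 1): HOM_ALT}


@dataclass
class VcfReadResult:
    calls: list[VariantCall] = field(default_factory=list)
    n_missing_depth: int = 0
    n_multiallelic_split: int = 0


def read_vcf(path: str | Path) -> VcfReadResult:
    """Read calls from a VCF; multi-allelic records are split per alt allele.

    Depth comes from FORMAT/DP (fallback INFO/DP), alt fraction from
    FORMAT/AF or VAF (fallback INFO). Records without depth are kept but
    flagged via ``n_missing_depth`` so the depth filter can count them.
    """
    result = VcfReadResult()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1:
                result.n_multiallelic_split += len(alts) - 1
            depth, af, gt_class = _extract_fields(rec)
            for i, alt in enumerate(alts):
                alt_af = af[i] if isinstance(af, tuple) else af
                if depth is None:
                    result.n_missing_depth += 1
                result.calls.append(VariantCall(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    depth=depth, alt_fraction=alt_af,
                    genotype_class=gt_class if len(alts) == 1 else UNASSIGNED,
                ))
    return result


def _extract_fields(rec) -> tuple[int | None, float | tuple | None, str]:
    depth = af = None
    gt_class = UNASSIGNED
    if rec.samples:
        sample = rec.samples[0]
        depth = sample.get("DP")
        af = sample.get("AF", sample.get("VAF"))
        gt = sample.get("GT")
        if gt is not None and None not in gt:
            gt_class = _GT_INV.get(tuple(gt), UNASSIGNED)
    if depth is None and "DP" in rec.header.info:
        depth = rec.info.get("DP")
    if af is None and "AF" in rec.header.info:
        af = rec.info.get("AF")
    if isinstance(af, tuple) and len(af) == 1:
        af = af[0]
    return (int(depth) if depth is not None else None, af, gt_class)


def write_vcf(calls, path: str | Path, sample_name: str = "sample") -> None:
    """Write bi-allelic calls as VCF v4.2 with DP, AF and GT fields."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Alt allele fraction">')
    for chrom in dict.fromkeys(c.chrom for c in calls):
        header.contigs.add(chrom)
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
            rec = out.new_record(
                contig=call.chrom, start=call.pos - 1, stop=call.pos,
                alleles=(call.ref, call.alt))
            if call.depth is not None:
                rec.samples[sample_name]["DP"] = call.depth
            if call.alt_fraction is not None:
                rec.samples[sample_name]["AF"] = call.alt_fraction
            rec.samples[sample_name]["GT"] = _GT[call.genotype_class]
            out.write(rec)
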