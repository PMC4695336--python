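"""Intron-retention metrics.

5' splice-site exon-intron boundary reads per million, intron/exon FPKM
ratios, and the stabilization-vs-splicing-defect classification of
changes between WT and mutant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genomics import AlignmentSet, Feature, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class IntronMetrics:
    intron_id: str
    boundary_rpm: float
    intron_fpkm: float
    exon_fpkm: float
    ratio: float  # NaN when exon_fpkm == 0
    library_id: str = ""


@dataclass
class IRCall:
    intron_id: str
    boundary_fold: float
    ratio_fold: float
    call: str  # stabilized / splicing_defect / unchanged


def fpkm(read_count: int, length_nt: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if length_nt <= 0 or total_mapped <= 0:
        raise ValueError("length and total_mapped must be > 0")
    return read_count * 1e9 / (length_nt * total_mapped)


def _junction_position(feature: Feature, intron: GenomicInterval) -> int:
    """Genomic coordinate of the 5' splice site of an intron."""
    return intron.start if feature.strand == "+" else intron.end


def count_boundary_reads(
    alignments: AlignmentSet,
    feature: Feature,
    intron: GenomicInterval,
    min_overhang: int = 3,
) -> int:
    """Reads spanning the 5'SS junction with >= min_overhang nt each side.

    The 5'SS is the transcript-orientation 5' end of the intron; the
    intron must have an upstream exon (always true for derived introns).
    """
    if not feature.introns:
        raise ValueError(f"feature {feature.id} has no introns")
    introns_g = feature.introns_genomic()
    if feature.strand == "+" and intron.start <= feature.start:
        raise ValueError("intron at transcript edge: no upstream exon")
    if feature.strand == "-" and intron.end >= feature.end:
        raise ValueError("intron at transcript edge: no upstream exon")
    j = _junction_position(feature, intron)
    reads = alignments.subset(feature.chrom, feature.strand)
    if reads.empty:
        return 0
    starts = reads["start"].to_numpy(int)
    ends = reads["end"].to_numpy(int)
    return int(((starts <= j - min_overhang) & (ends >= j + min_overhang)).sum())


def compute_intron_metrics(
    alignments: AlignmentSet,
    feature: Feature,
    min_overhang: int = 3,
) -> list[IntronMetrics]:
    """Per-intron boundary RPM, intron FPKM and intron/exon FPKM ratio.

    Intron and exon read counts use read-midpoint membership; exon FPKM
    is computed over the union of the gene's exons.
    """
    if not feature.introns:
        raise ValueError(f"feature {feature.id} has no introns")
    reads = alignments.subset(feature.chrom, feature.strand)
    mid = (
        (reads["start"].to_numpy(int) + reads["end"].to_numpy(int)) // 2
        if not reads.empty
        else np.empty(0, dtype=int)
    )
    total = alignments.total_mapped
    exon_count = 0
    for e in feature.exons:
        exon_count += int(((mid >= e.start) & (mid < e.end)).sum())
    exon_fpkm = fpkm(exon_count, feature.exonic_length, total)

    out = []
    for i, intron in enumerate(feature.introns):
        n_boundary = count_boundary_reads(alignments, feature, intron, min_overhang)
        n_intron = int(((mid >= intron.start) & (mid < intron.end)).sum())
        ifpkm = fpkm(n_intron, intron.length, total)
        if exon_fpkm > 0:
            ratio = ifpkm / exon_fpkm
        else:
            ratio = float("nan")
            log.warning("exon FPKM is 0 for %s; ratio undefined", feature.id)
        out.append(
            IntronMetrics(
                intron_id=feature.intron_id(i),
                boundary_rpm=n_boundary / total * 1e6,
                intron_fpkm=ifpkm,
                exon_fpkm=exon_fpkm,
                ratio=ratio,
                library_id=alignments.library_id,
            )
        )
    return out


def classify_ir_change(
    wt: IntronMetrics,
    mut: IntronMetrics,
    boundary_threshold: float = 2.0,
    ratio_threshold: float = 2.0,
    rpm_pseudocount: float = 0.1,
    ratio_pseudocount: float = 0.01,
) -> IRCall:
    """Classify the WT->mutant change at one intron.

    An increase in 5'SS boundary reads (> boundary_threshold fold, per
    million) with an unchanged intron/exon ratio indicates stabilization
    of the pre-mRNA; an increase in both indicates a splicing defect.
    Pseudocounts keep folds finite at zero signal.
    """
    if wt.intron_id != mut.intron_id:
        raise ValueError("metrics are for different introns")
    boundary_fold = (mut.boundary_rpm + rpm_pseudocount) / (wt.boundary_rpm + rpm_pseudocount)
    wt_ratio = wt.ratio if np.isfinite(wt.ratio) else 0.0
    mut_ratio = mut.ratio if np.isfinite(mut.ratio) else 0.0
    ratio_fold = (mut_ratio + ratio_pseudocount) / (wt_ratio + ratio_pseudocount)
    if boundary_fold > boundary_threshold:
        call = "splicing_defect" if ratio_fold > ratio_threshold else "stabilized"
    else:
        call = "unchanged"
    return IRCall(wt.intron_id, float(boundary_fold), float(ratio_fold), call)
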