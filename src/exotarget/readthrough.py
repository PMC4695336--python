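"""Transcription readthrough downstream of annotated 3' ends.

Quantifies reads in a window downstream of each gene (truncated at the
next same-strand feature) and assigns one of three readthrough classes
by combining the downstream fold change with the gene-body DE call:
class 1 = body up, class 2 = body unchanged (leaky-termination
degradation substrates), class 3 = body down (termination defect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genomics import AlignmentSet, Feature, GenomeAnnotation, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class ReadthroughRecord:
    gene_id: str
    downstream_rpm_wt: float
    downstream_rpm_mut: float
    downstream_fold: float  # NaN when the window is occluded
    body_call: str
    rt_class: int  # 1, 2, 3 or 0 for none
    window: GenomicInterval | None
    flagged: bool = False


def downstream_signal(
    alignments: AlignmentSet,
    gene: Feature,
    annotation: GenomeAnnotation,
    window_nt: int = 300,
) -> tuple[float, GenomicInterval | None]:
    """Reads per million with midpoint in the downstream window.

    The window is [3'end, 3'end + window_nt) in transcript orientation,
    truncated at the first same-strand annotated feature.  A fully
    occluded window yields (NaN, None) with a warning.
    """
    if gene.strand == "+":
        w_start = gene.end
        w_end = min(gene.end + window_nt, annotation.chrom_lengths[gene.chrom])
        nxt = annotation.next_feature_start(gene.chrom, gene.strand, gene.end)
        if nxt is not None:
            w_end = min(w_end, nxt)
    else:
        w_end = gene.start
        w_start = max(gene.start - window_nt, 0)
        prv = annotation.prev_feature_end(gene.chrom, gene.strand, gene.start)
        if prv is not None:
            w_start = max(w_start, prv)
    if w_end <= w_start:
        log.warning("downstream window of %s fully occluded", gene.id)
        return float("nan"), None
    window = GenomicInterval(gene.chrom, w_start, w_end, gene.strand)
    reads = alignments.subset(gene.chrom, gene.strand)
    if reads.empty:
        return 0.0, window
    mid = (reads["start"].to_numpy(int) + reads["end"].to_numpy(int)) // 2
    n = int(((mid >= w_start) & (mid < w_end)).sum())
    return n / alignments.total_mapped * 1e6, window


_CLASS_BY_CALL = {"up": 1, "unchanged": 2, "down": 3}


def classify_readthrough(
    gene_id: str,
    rpm_wt: float,
    rpm_mut: float,
    body_call: str,
    window: GenomicInterval | None,
    rt_threshold: float = 2.0,
    rpm_pseudocount: float = 0.1,
) -> ReadthroughRecord:
    """Assign the readthrough class for one gene.

    Classes 1-3 require downstream_fold > rt_threshold; the class itself
    is the gene-body DE call (up/unchanged/down -> 1/2/3).  Occluded
    windows (NaN rpm) give class 0 with a flag.
    """
    if not (np.isfinite(rpm_wt) and np.isfinite(rpm_mut)) or window is None:
        return ReadthroughRecord(
            gene_id, rpm_wt, rpm_mut, float("nan"), body_call, 0, window, flagged=True
        )
    fold = (rpm_mut + rpm_pseudocount) / (rpm_wt + rpm_pseudocount)
    rt_class = _CLASS_BY_CALL[body_call] if fold > rt_threshold else 0
    return ReadthroughRecord(gene_id, rpm_wt, rpm_mut, float(fold), body_call, rt_class, window)
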