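"""CRAC binding analysis.

Per-feature read counting, read-cluster calling, k-mer enrichment against
mononucleotide-shuffled backgrounds, abundance-normalized binding
enrichment, pA+/pA- classification and intronic-binding fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomics import (
    AlignmentSet,
    Feature,
    GenomeAnnotation,
    GenomeSequence,
    GenomicInterval,
    fetch_sequence,
)
from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class FeatureCounts:
    """Result of assigning reads to annotated features.

    ``sense`` and ``antisense`` are per-feature counts; ``intergenic`` is
    the number of reads overlapping no annotated feature on either
    strand.  The three buckets partition the assigned reads.
    """

    sense: dict[str, int]
    antisense: dict[str, int]
    intergenic: int
    n_reads: int

    def total_assigned(self) -> int:
        return sum(self.sense.values()) + sum(self.antisense.values()) + self.intergenic


def assign_reads_to_features(
    alignments: AlignmentSet, annotation: GenomeAnnotation
) -> FeatureCounts:
    """Assign each read to exactly one feature.

    A read goes to the same-strand feature with maximal overlap; ties are
    broken by smaller feature (specific beats broad), then lexicographic
    id.  Reads with only opposite-strand overlap are tallied per feature
    as antisense; reads overlapping nothing count as intergenic.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for f in annotation:
        trees.setdefault((f.chrom, f.strand), IntervalTree()).addi(f.start, f.end, f)

    sense: dict[str, int] = {f.id: 0 for f in annotation}
    antisense: dict[str, int] = {f.id: 0 for f in annotation}
    intergenic = 0

    flip = {"+": "-", "-": "+"}
    for row in alignments.df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        best = _best_feature(trees.get((row.chrom, row.strand)), start, end)
        if best is not None:
            sense[best.id] += 1
            continue
        best = _best_feature(trees.get((row.chrom, flip[row.strand])), start, end)
        if best is not None:
            antisense[best.id] += 1
        else:
            intergenic += 1
    return FeatureCounts(sense, antisense, intergenic, len(alignments.df))


def _best_feature(tree: IntervalTree | None, start: int, end: int) -> Feature | None:
    if tree is None:
        return None
    hits = tree.overlap(start, end)
    if not hits:
        return None
    def key(iv):
        f: Feature = iv.data
        overlap = min(end, f.end) - max(start, f.start)
        return (-overlap, f.interval.length, f.id)
    return min(hits, key=key).data


# ---------------------------------------------------------------------------
# cluster calling

@dataclass
class Cluster:
    """A contiguous pile of reads above the coverage threshold."""

    interval: GenomicInterval
    height: int
    n_reads: int
    sequence: str


def call_clusters(
    alignments: AlignmentSet,
    genome: GenomeSequence,
    min_height: int = 5,
    min_length: int = 12,
    merge_gap: int = 3,
) -> list[Cluster]:
    """Call read clusters per chromosome strand.

    Clusters are maximal intervals with per-base coverage >= min_height,
    merged when separated by < merge_gap nt, and discarded when shorter
    than min_length.  Sequences are sense strand.
    """
    clusters: list[Cluster] = []
    for chrom, seq in genome.chroms.items():
        L = len(seq)
        for strand in ("+", "-"):
            reads = alignments.subset(chrom, strand)
            if reads.empty:
                continue
            starts = reads["start"].to_numpy(int)
            ends = np.minimum(reads["end"].to_numpy(int), L)
            cov = np.zeros(L + 1, dtype=np.int64)
            np.add.at(cov, starts, 1)
            np.add.at(cov, ends, -1)
            cov = np.cumsum(cov)[:L]
            above = cov >= min_height
            if not above.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
            runs = list(zip(edges[::2], edges[1::2]))
            merged = [list(runs[0])]
            for s, e in runs[1:]:
                if s - merged[-1][1] < merge_gap:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            for s, e in merged:
                if e - s < min_length:
                    continue
                iv = GenomicInterval(chrom, int(s), int(e), strand)
                n_reads = int(((starts < e) & (ends > s)).sum())
                clusters.append(
                    Cluster(iv, int(cov[s:e].max()), n_reads, fetch_sequence(genome, iv))
                )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.strand))
    return clusters


# ---------------------------------------------------------------------------
# k-mer enrichment

@dataclass
class KmerStat:
    kmer: str
    observed: int
    bg_mean: float
    bg_sd: float
    z: float  # NaN when bg_sd == 0
    p_emp: float
    q: float


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)


def _kmer_counts(codes: np.ndarray, k: int, n_kmers: int) -> np.ndarray:
    """Occurrence counts of every k-mer (overlapping); windows with N skipped."""
    if len(codes) < k:
        return np.zeros(n_kmers, dtype=np.int64)
    valid = codes >= 0
    idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
    ok = np.ones(len(codes) - k + 1, dtype=bool)
    for j in range(k):
        idx = idx * 4 + np.where(valid[j : j + len(idx)], codes[j : j + len(idx)], 0)
        ok &= valid[j : j + len(idx)]
    return np.bincount(idx[ok], minlength=n_kmers)


def _decode(index: int, k: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(k):
        out.append(bases[index % 4])
        index //= 4
    return "".join(reversed(out))


def kmer_enrichment(
    clusters: list[Cluster],
    k: int = 6,
    n_shuffles: int = 100,
    seed: int = 0,
) -> list[KmerStat]:
    """k-mer enrichment in cluster sequences vs shuffled backgrounds.

    Observed counts sum overlapping occurrences over all cluster
    sequences.  The background shuffles each cluster sequence
    independently (mononucleotide shuffle, i.e. a random permutation of
    its letters) n_shuffles times and recounts.  The empirical p-value
    uses the +1/+1 correction so it is never 0; BH adjustment runs across
    all k-mers with observed > 0.  Results are ranked by z descending
    (undefined z, from shuffle-invariant composition, sorts last).
    """
    seqs = [_encode(c.sequence.upper()) for c in clusters if len(c.sequence) >= k]
    if not seqs:
        raise ValueError(f"no cluster sequence of length >= {k}")
    n_kmers = 4 ** k
    observed = np.zeros(n_kmers, dtype=np.int64)
    for s in seqs:
        observed += _kmer_counts(s, k, n_kmers)

    rng = np.random.default_rng(seed)
    bg = np.zeros((n_shuffles, n_kmers), dtype=np.int64)
    for i in range(n_shuffles):
        for s in seqs:
            bg[i] += _kmer_counts(rng.permutation(s), k, n_kmers)

    keep = np.flatnonzero(observed > 0)
    bg_mean = bg[:, keep].mean(axis=0)
    bg_sd = bg[:, keep].std(axis=0, ddof=1)
    obs = observed[keep].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bg_sd > 0, (obs - bg_mean) / bg_sd, np.nan)
    p_emp = (1.0 + (bg[:, keep] >= observed[keep]).sum(axis=0)) / (1.0 + n_shuffles)
    q = bh_adjust(p_emp)

    stats = [
        KmerStat(
            kmer=_decode(int(i), k),
            observed=int(observed[i]),
            bg_mean=float(bg_mean[j]),
            bg_sd=float(bg_sd[j]),
            z=float(z[j]),
            p_emp=float(p_emp[j]),
            q=float(q[j]),
        )
        for j, i in enumerate(keep)
    ]
    stats.sort(key=lambda s: (-(s.z if math.isfinite(s.z) else -math.inf), s.kmer))
    return stats


# ---------------------------------------------------------------------------
# abundance-normalized enrichment and pA classification

@dataclass
class EnrichmentRecord:
    feature_id: str
    crac_count: int
    abundance: float  # NaN when missing from the abundance table
    enrichment: float  # NaN when abundance missing
    fclass: str
    pA: str = "NA"


def compute_enrichment(
    counts: dict[str, int],
    abundance: pd.Series,
    annotation: GenomeAnnotation,
    pseudocount: float = 0.1,
) -> list[EnrichmentRecord]:
    """CRAC counts normalized to transcript abundance.

    enrichment = crac_count / (abundance + pseudocount).  Features missing
    from the abundance table get NaN abundance and are excluded from
    ranking (logged count).
    """
    records = []
    n_missing = 0
    for fid, n in counts.items():
        fclass = annotation.features[fid].fclass if fid in annotation.features else "NA"
        if fid in abundance.index and np.isfinite(abundance[fid]):
            ab = float(abundance[fid])
            enr = n / (ab + pseudocount)
        else:
            ab, enr = float("nan"), float("nan")
            n_missing += 1
        records.append(EnrichmentRecord(fid, int(n), ab, enr, fclass))
    if n_missing:
        log.warning("%d features missing from the abundance table", n_missing)
    records.sort(key=lambda r: -(r.enrichment if math.isfinite(r.enrichment) else -math.inf))
    return records


@dataclass
class PolyAConfig:
    cutoff: float = 5.0
    # "depletion": pA- iff normalized oligo-dT/total ratio <= 1/cutoff
    # "enrichment": pA+ iff ratio >= cutoff
    direction: str = "depletion"

    def __post_init__(self) -> None:
        if self.cutoff <= 1:
            raise ValueError("cutoff must be > 1")
        if self.direction not in ("depletion", "enrichment"):
            raise ValueError(f"unknown direction {self.direction!r}")


def classify_polyA(
    abundance_polyA: pd.Series,
    abundance_total: pd.Series,
    config: PolyAConfig | None = None,
) -> dict[str, str]:
    """Classify transcripts as pA+ or pA- from oligo-dT vs total abundance.

    Both tables are median-normalized over shared features; the ratio
    R = normalized oligo-dT / normalized total is compared against the
    fold cutoff (default 5.0).  Features absent from either table get NA.
    """
    config = config or PolyAConfig()
    shared = abundance_polyA.index.intersection(abundance_total.index)
    pa = abundance_polyA.loc[shared].astype(float)
    tot = abundance_total.loc[shared].astype(float)
    ok = (pa > 0) & (tot > 0)
    pa_med, tot_med = pa[ok].median(), tot[ok].median()
    status: dict[str, str] = {}
    for fid in abundance_polyA.index.union(abundance_total.index):
        if fid not in shared or not ok.get(fid, False):
            status[fid] = "NA"
            continue
        r = (pa[fid] / pa_med) / (tot[fid] / tot_med)
        if config.direction == "depletion":
            status[fid] = "pA-" if r <= 1.0 / config.cutoff else "pA+"
        else:
            status[fid] = "pA+" if r >= config.cutoff else "pA-"
    return status


# ---------------------------------------------------------------------------
# intronic binding

def intronic_binding_fraction(feature: Feature, alignments: AlignmentSet) -> float:
    """Fraction of a gene's reads whose midpoint lies in an intron.

    NaN when the gene has no reads; error for intronless features.
    """
    if not feature.introns:
        raise ValueError(f"feature {feature.id} has no introns")
    reads = alignments.subset(feature.chrom, feature.strand)
    if reads.empty:
        return float("nan")
    mid = ((reads["start"].to_numpy(int) + reads["end"].to_numpy(int)) // 2)
    in_feat = (mid >= feature.start) & (mid < feature.end)
    n_feat = int(in_feat.sum())
    if n_feat == 0:
        return float("nan")
    in_intron = np.zeros(len(mid), dtype=bool)
    for intron in feature.introns:
        in_intron |= (mid >= intron.start) & (mid < intron.end)
    return float((in_intron & in_feat).sum() / n_feat)
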