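"""Coordinate model and genome/annotation/read I/O.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based
closed) is converted at the I/O boundary.  Reads and features are strand
specific everywhere: antisense signal is never merged into sense counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: feature classes the annotation layer understands
FEATURE_CLASSES = frozenset(
    {"mRNA", "ncRNA", "snRNA", "snoRNA", "rRNA", "tRNA", "pseudogene", "intergenic"}
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def derive_introns(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Gaps between consecutive exons, in genomic order.

    Exons must be non-overlapping; they are sorted internally.  A single
    exon yields no introns.
    """
    if not exons:
        raise ValueError("need at least one exon")
    ordered = sorted(exons, key=lambda e: e.start)
    introns: list[GenomicInterval] = []
    for left, right in zip(ordered, ordered[1:]):
        if right.start < left.end:
            raise ValueError(f"overlapping exons [{left.start},{left.end}) and [{right.start},{right.end})")
        if right.start > left.end:
            introns.append(GenomicInterval(left.chrom, left.end, right.start, left.strand))
    return introns


@dataclass
class Feature:
    """A gene model: stranded span, exons and derived introns.

    ``exons`` and ``introns`` are stored 5'->3' in transcript orientation
    (genomic order for '+', reversed for '-').
    """

    id: str
    fclass: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    introns: list[GenomicInterval] = field(default_factory=list)

    @classmethod
    def build(
        cls, id: str, fclass: str, chrom: str, strand: str, exons: Iterable[tuple[int, int]]
    ) -> "Feature":
        if fclass not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {fclass!r} for {id}")
        ex = sorted(
            (GenomicInterval(chrom, s, e, strand) for s, e in exons), key=lambda x: x.start
        )
        if not ex:
            raise ValueError(f"feature {id} has no exons")
        introns = derive_introns(ex)
        span = GenomicInterval(chrom, ex[0].start, ex[-1].end, strand)
        if strand == "-":
            ex = ex[::-1]
            introns = introns[::-1]
        return cls(id=id, fclass=fclass, interval=span, exons=ex, introns=introns)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def exons_genomic(self) -> list[GenomicInterval]:
        return sorted(self.exons, key=lambda e: e.start)

    def introns_genomic(self) -> list[GenomicInterval]:
        return sorted(self.introns, key=lambda e: e.start)

    def intron_id(self, i: int) -> str:
        """Identifier of the i-th intron in transcript orientation."""
        return f"{self.id}.i{i + 1}"

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


class GenomeAnnotation:
    """Feature collection indexed by id and by (chrom, strand) position."""

    def __init__(self, features: Iterable[Feature], chrom_lengths: Mapping[str, int]):
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        self.features: dict[str, Feature] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for f in features:
            if f.id in self.features:
                raise ValueError(f"duplicate feature id {f.id}")
            clen = self.chrom_lengths.get(f.chrom)
            if clen is None:
                raise ValueError(f"feature {f.id} on unknown chromosome {f.chrom}")
            if f.end > clen:
                raise ValueError(f"feature {f.id} extends beyond chromosome end ({f.end} > {clen})")
            self.features[f.id] = f
            key = (f.chrom, f.strand)
            self._trees.setdefault(key, IntervalTree()).addi(f.start, f.end, f.id)
        self._check_intergenic()

    def _check_intergenic(self) -> None:
        for f in self.features.values():
            if f.fclass != "intergenic":
                continue
            for other in self.overlapping(f.chrom, f.strand, f.start, f.end):
                if other.id != f.id and other.fclass != "intergenic":
                    raise ValueError(
                        f"intergenic feature {f.id} overlaps {other.id} on the same strand"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self.chrom_lengths == other.chrom_lengths and self.features == other.features

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features.values())

    def overlapping(self, chrom: str, strand: str, start: int, end: int) -> list[Feature]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [self.features[iv.data] for iv in tree.overlap(start, end)]

    def next_feature_start(self, chrom: str, strand: str, pos: int) -> int | None:
        """Leftmost same-strand feature start at or after ``pos``."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return None
        starts = [iv.begin for iv in tree if iv.begin >= pos]
        return min(starts) if starts else None

    def prev_feature_end(self, chrom: str, strand: str, pos: int) -> int | None:
        """Rightmost same-strand feature end at or before ``pos``."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return None
        ends = [iv.end for iv in tree if iv.end <= pos]
        return max(ends) if ends else None

    def iter_introns(self) -> Iterator[tuple[str, Feature, GenomicInterval]]:
        """Yield (intron_id, gene, intron) over all introns, transcript order."""
        for f in self.features.values():
            for i, intron in enumerate(f.introns):
                yield f.intron_id(i), f, intron


@dataclass
class GenomeSequence:
    """Per-chromosome nucleotide strings over {A,C,G,T,N}."""

    chroms: dict[str, str]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def validate_against(self, annotation: GenomeAnnotation) -> None:
        if self.chrom_lengths != annotation.chrom_lengths:
            raise ValueError("sequence lengths do not match annotation chrom_lengths")


def fetch_sequence(genome: GenomeSequence, interval: GenomicInterval) -> str:
    """Sense-strand sequence of an interval (reverse complement on '-')."""
    seq = genome.chroms.get(interval.chrom)
    if seq is None:
        raise KeyError(f"unknown chromosome {interval.chrom}")
    if interval.end > len(seq):
        raise ValueError(f"interval [{interval.start},{interval.end}) beyond chromosome end")
    sub = seq[interval.start : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> GenomeSequence:
    from Bio import SeqIO

    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not chroms:
        raise ValueError(f"no sequences in {path}")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 gene annotation.

    Gene records carry the feature class in an ``fclass=`` attribute; when
    absent, the GFF3 type column is used if it names a known class, else
    the record is rejected (logged).  Exon rows reference their gene via
    ``Parent=``.  Chromosome lengths come from ``##sequence-region``
    directives when present, else from the maximal feature end.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    chrom_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 3:
            chrom_lengths[parts[1]] = int(parts[3]) if len(parts) >= 4 else int(parts[2])

    features: list[Feature] = []
    for rec in db.all_features():
        if rec.featuretype == "exon" or "Parent" in rec.attributes:
            continue
        fid = rec.attributes.get("ID", [rec.id])[0]
        fclass = rec.attributes.get("fclass", [None])[0]
        if fclass is None:
            fclass = rec.featuretype if rec.featuretype in FEATURE_CLASSES else None
        if fclass not in FEATURE_CLASSES:
            log.warning("rejecting %s: unknown feature class %r", fid, fclass)
            continue
        exon_rows = [
            (c.start - 1, c.end)  # 1-based closed -> 0-based half-open
            for c in db.children(rec.id, featuretype="exon")
        ]
        if not exon_rows:
            exon_rows = [(rec.start - 1, rec.end)]
        try:
            features.append(Feature.build(fid, fclass, rec.seqid, rec.strand, exon_rows))
        except ValueError as exc:
            log.warning("rejecting %s: %s", fid, exc)
            continue

    if not chrom_lengths:
        for f in features:
            chrom_lengths[f.chrom] = max(chrom_lengths.get(f.chrom, 0), f.end)
    return GenomeAnnotation(features, chrom_lengths)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for f in sorted(annotation, key=lambda x: (x.chrom, x.start, x.id)):
            attrs = f"ID={f.id};fclass={f.fclass}"
            fh.write(
                f"{f.chrom}\texotarget\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(f.exons_genomic(), start=1):
                fh.write(
                    f"{f.chrom}\texotarget\texon\t{ex.start + 1}\t{ex.end}\t.\t{f.strand}\t.\t"
                    f"ID={f.id}.e{i};Parent={f.id}\n"
                )


# ---------------------------------------------------------------------------
# Read intervals (BED6 / SAM / BAM)

@dataclass
class AlignmentSet:
    """Uniquely mapped read intervals plus the library-size denominator.

    ``df`` has columns chrom/start/end/strand; ``total_mapped`` is the
    number of uniquely mapped reads in the library and is the denominator
    for all per-million normalization.
    """

    df: pd.DataFrame
    total_mapped: int
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.total_mapped < len(self.df):
            raise ValueError("total_mapped must be >= number of reads")
        self.df = self.df.reset_index(drop=True)
        self._by_key: dict[tuple[str, str], pd.DataFrame] | None = None

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, chrom: str, strand: str) -> pd.DataFrame:
        """Reads on one chromosome strand (cached)."""
        if self._by_key is None:
            self._by_key = {key: grp for key, grp in self.df.groupby(["chrom", "strand"], sort=False)}
        return self._by_key.get((chrom, strand), self.df.iloc[0:0])

    def intervals(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)

    @staticmethod
    def concat(sets: list["AlignmentSet"], library_id: str = "pooled") -> "AlignmentSet":
        df = pd.concat([s.df for s in sets], ignore_index=True)
        return AlignmentSet(df, sum(s.total_mapped for s in sets), library_id)


def read_alignments(
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
    total_mapped: int | None = None,
    library_id: str | None = None,
) -> AlignmentSet:
    """Load stranded read intervals from BED6, SAM or BAM.

    SAM/BAM records are reduced to chrom/start/end/strand of primary,
    uniquely mapped alignments (secondary/supplementary/unmapped are
    dropped).  Reads beyond chromosome bounds are rejected with a logged
    count.  ``total_mapped`` defaults to the number of reads kept.
    """
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam"}:
        df = _read_sam(path)
    else:
        df = _read_bed6(path)
    if chrom_lengths is not None:
        lens = df["chrom"].map(chrom_lengths)
        ok = (df["start"] >= 0) & lens.notna() & (df["end"] <= lens.fillna(-1))
        n_bad = int((~ok).sum())
        if n_bad:
            log.warning("rejected %d out-of-bounds reads from %s", n_bad, path)
            df = df[ok].reset_index(drop=True)
    return AlignmentSet(
        df,
        total_mapped if total_mapped is not None else len(df),
        library_id or path.stem,
    )


def _read_bed6(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns, got {len(parts)}")
            chrom, start, end, _name, _score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            if not (0 <= s < e):
                raise ValueError(f"{path}:{lineno}: invalid interval [{s},{e})")
            rows.append((chrom, s, e, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def _read_sam(path: Path) -> pd.DataFrame:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    rows = []
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def write_bed6(alignments: AlignmentSet, path: str | Path, name_prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(alignments.df.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name_prefix}{i}\t0\t{row.strand}\n")
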