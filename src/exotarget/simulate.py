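"""Synthetic genome, annotation, truth set and CRAC / RNA-seq libraries.

The generator emulates the statistical structure the downstream analysis
assumes: a compact two-chromosome genome carrying protein-coding genes
(a fraction with short introns), pA+ and pA- ncRNAs, sn/snoRNAs and
unannotated "intergenic" transcripts; a subset of introns carry planted
U(U/C/G)AAAC motifs (written as DNA, T(T/C/G)AAAC) and act as
decay-promoting introns; CRAC reads pile up around planted motifs; WT and
mutant RNA-seq libraries carry planted fold changes, intron-retention
increases and three classes of downstream-of-gene readthrough.

Everything is deterministic under a fixed seed; all files are plain text
(FASTA, GFF3, BED6, TSV, JSON).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import (
    AlignmentSet,
    Feature,
    GenomeAnnotation,
    GenomeSequence,
    GenomicInterval,
    reverse_complement,
)

DSR_VARIANT_MIDDLE = "TCG"  # U(U/C/G)AAAC, written in DNA

# gene-role labels used in the truth table
IR_CATEGORIES = ("stabilized", "splicing_defect", "unchanged")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions every seeded test and the
    acceptance run use: a 2 x 250 kb genome, 150 features, 50k CRAC reads
    and 200k RNA-seq reads per library in triplicate.
    """

    seed: int = 1
    n_chrom: int = 2
    chrom_length: int = 250_000

    n_mrna: int = 84
    n_ncrna: int = 36
    n_snrna: int = 2
    n_snorna: int = 4
    n_intergenic: int = 24
    intron_fraction: float = 0.45  # of mRNAs

    n_decay_introns: int = 12
    motif_copies_min: int = 1
    motif_copies_max: int = 6
    n_exonic_targets: int = 20  # ncRNA/intergenic transcripts with exonic motifs
    n_splicing_defect: int = 6
    n_readthrough_per_class: int = 6
    n_down_genes: int = 20

    crac_depth: int = 50_000
    rnaseq_depth: int = 200_000
    n_replicates: int = 3
    read_length: int = 50
    crac_read_length: int = 30
    nb_dispersion: float = 0.05

    expr_min: float = 1.0
    expr_max: float = 1000.0
    # intron-containing genes are drawn well expressed: junction metrics
    # are count-based and only informative at moderate coverage (the
    # study's intron-containing exemplars are ribosomal-protein-class
    # genes, which are highly expressed)
    high_expr_min: float = 50.0
    # genes carrying a planted mutant effect (decay introns, readthrough)
    # sit in a moderate band: abundant enough to measure, but regulated
    # transcripts are not the most abundant ones, so their accumulation
    # does not dominate mutant library depth
    planted_expr_min: float = 80.0
    planted_expr_max: float = 400.0
    # exonic-target ncRNA/intergenic transcripts are low abundance (the
    # binding-enrichment anticorrelation: high CRAC enrichment on
    # low-abundance transcripts)
    target_expr_max: float = 100.0

    target_affinity: float = 50.0
    motif_sigma: float = 15.0

    log2fc_up: float = 2.0
    log2fc_down: float = -1.5
    ir_baseline_unspliced: float = 0.08
    ir_defect_unspliced: float = 0.35
    rt_signal_mut: float = 0.30  # downstream reads as a fraction of body depth
    rt_signal_wt: float = 0.02
    rt_length: int = 200

    pa_minus_fraction: float = 0.5  # of ncRNA and intergenic transcripts
    pa_depletion: float = 20.0  # oligo-dT abundance = total / this for pA-

    min_gap: int = 200
    max_gap: int = 2000

    def validate(self) -> None:
        counts = [
            self.n_chrom, self.chrom_length, self.n_mrna, self.n_ncrna,
            self.crac_depth, self.rnaseq_depth, self.n_replicates,
            self.read_length, self.crac_read_length,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0 <= self.intron_fraction <= 1):
            raise ValueError("intron_fraction must be in [0,1]")
        if not (1 <= self.motif_copies_min <= self.motif_copies_max <= 6):
            raise ValueError("motif copies must satisfy 1 <= min <= max <= 6")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Per-gene ground truth, consistent with the emitted annotation.

    ``genes`` has one row per feature: fclass, expression, abundances,
    pA status, CRAC affinity, planted mutant log2FC, IR category,
    readthrough class, decay-intron flag and planted motif positions.
    ``intron_motif_counts`` records, for every intron, the number of
    sense-strand TNAAAC hits found by scanning the emitted sequence
    (planted plus chance background).
    """

    genes: pd.DataFrame
    intron_motif_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "intron_motif_counts": self.intron_motif_counts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_json_default)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = pd.DataFrame(payload["genes"]).set_index("gene_id", drop=False)
        return cls(genes=genes, intron_motif_counts=payload["intron_motif_counts"])


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# genome + annotation + truth

def simulate_genome(config: SimConfig) -> tuple[GenomeSequence, GenomeAnnotation, SimTruth]:
    """Build the toy genome: sequence, annotation and ground truth.

    Genes are placed without same-strand overlap (in fact without any
    overlap), separated by >= ``min_gap`` nt.  Decay-intron genes receive
    1-6 sense-strand T(T/C/G)AAAC copies inside their first intron;
    exonic-target ncRNA/intergenic transcripts receive 1-3 copies in
    their exon.  Background sequence is i.i.d. uniform ACGT.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    roles = _assign_roles(config, rng)
    genes = _place_genes(config, rng, roles)

    # background sequence
    chroms = {}
    for i in range(config.n_chrom):
        arr = rng.integers(0, 4, size=config.chrom_length)
        chroms[f"chr{i + 1}"] = "".join("ACGT"[b] for b in arr)

    # plant motifs (overwrite background)
    seq_arrays = {c: list(s) for c, s in chroms.items()}
    for g in genes:
        positions = []
        if g["n_motifs"] > 0:
            positions = _plant_motifs(seq_arrays[g["chrom"]], g, rng)
        g["motif_positions"] = positions
    chroms = {c: "".join(a) for c, a in seq_arrays.items()}
    genome = GenomeSequence(chroms)

    features = [
        Feature.build(g["gene_id"], g["fclass"], g["chrom"], g["strand"], g["exons"])
        for g in genes
    ]
    annotation = GenomeAnnotation(features, genome.chrom_lengths)

    truth = _build_truth(config, rng, genes, annotation, genome)
    return genome, annotation, truth


def _assign_roles(config: SimConfig, rng: np.random.Generator) -> dict:
    """Pick disjoint planted gene sets for every truth category."""
    n_intron = int(round(config.n_mrna * config.intron_fraction))
    need = config.n_decay_introns + config.n_splicing_defect
    if n_intron < need:
        raise ValueError("not enough intron-containing mRNAs for the planted IR classes")
    n_rt = 3 * config.n_readthrough_per_class
    if config.n_mrna - n_intron < n_rt:
        raise ValueError("not enough intronless mRNAs for the readthrough classes")

    mrna_idx = list(range(config.n_mrna))
    rng.shuffle(mrna_idx)
    intron_genes = mrna_idx[:n_intron]
    intronless = mrna_idx[n_intron:]

    decay = set(intron_genes[: config.n_decay_introns])
    defect = set(intron_genes[config.n_decay_introns : need])
    rt1 = set(intronless[: config.n_readthrough_per_class])
    rt2 = set(intronless[config.n_readthrough_per_class : 2 * config.n_readthrough_per_class])
    rt3 = set(intronless[2 * config.n_readthrough_per_class : n_rt])

    # downregulated genes: split over intronless mRNAs / ncRNAs / intergenic
    free_mrna = [i for i in intronless[n_rt:]]
    n_down_m = min(len(free_mrna), max(0, config.n_down_genes - 12))
    down_mrna = set(free_mrna[:n_down_m])
    remaining_down = config.n_down_genes - n_down_m

    nc_idx = list(range(config.n_ncrna))
    rng.shuffle(nc_idx)
    n_nc_targets = min(config.n_ncrna, (config.n_exonic_targets * 3) // 5)
    nc_targets = set(nc_idx[:n_nc_targets])
    down_nc = set(nc_idx[n_nc_targets : n_nc_targets + remaining_down // 2])

    int_idx = list(range(config.n_intergenic))
    rng.shuffle(int_idx)
    n_int_targets = config.n_exonic_targets - n_nc_targets
    int_targets = set(int_idx[:n_int_targets])
    down_int = set(
        int_idx[n_int_targets : n_int_targets + (remaining_down - remaining_down // 2)]
    )

    return {
        "intron_genes": set(intron_genes),
        "decay": decay,
        "defect": defect,
        "rt1": rt1,
        "rt2": rt2,
        "rt3": rt3,
        "down_mrna": down_mrna,
        "nc_targets": nc_targets,
        "down_nc": down_nc,
        "int_targets": int_targets,
        "down_int": down_int,
    }


def _gene_structures(config: SimConfig, rng: np.random.Generator, roles: dict) -> list[dict]:
    """Draw exon/intron structure and role labels for every feature."""
    genes: list[dict] = []

    def expression(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for i in range(config.n_mrna):
        gid = f"mRNA_{i + 1:03d}"
        has_intron = i in roles["intron_genes"]
        is_decay = i in roles["decay"]
        is_defect = i in roles["defect"]
        rt_class = 1 if i in roles["rt1"] else 2 if i in roles["rt2"] else 3 if i in roles["rt3"] else 0
        n_introns = (1 + int(rng.integers(0, 2))) if has_intron else 0
        exon_lens = [int(rng.integers(150, 601)) for _ in range(n_introns + 1)]
        intron_lens = []
        for k in range(n_introns):
            if is_decay and k == 0:
                intron_lens.append(int(rng.integers(160, 261)))
            else:
                intron_lens.append(int(rng.integers(60, 151)))
        if is_decay:
            log2fc, ir_cat = config.log2fc_up, "stabilized"
        elif is_defect:
            log2fc, ir_cat = 0.0, "splicing_defect"
        elif rt_class == 1:
            log2fc, ir_cat = config.log2fc_up, "unchanged"
        elif rt_class == 3:
            log2fc, ir_cat = config.log2fc_down, "unchanged"
        elif i in roles["down_mrna"]:
            log2fc, ir_cat = config.log2fc_down, "unchanged"
        else:
            log2fc, ir_cat = 0.0, "unchanged"
        n_motifs = int(rng.integers(config.motif_copies_min, config.motif_copies_max + 1)) if is_decay else 0
        if is_decay or rt_class > 0:
            expr = expression(config.planted_expr_min, config.planted_expr_max)
        elif has_intron:
            expr = expression(config.high_expr_min, config.expr_max)
        else:
            expr = expression(config.expr_min, config.expr_max)
        genes.append(dict(
            gene_id=gid, fclass="mRNA", exon_lens=exon_lens, intron_lens=intron_lens,
            expression=expr, affinity=config.target_affinity if is_decay else 1.0,
            log2fc=log2fc, ir_category=ir_cat, rt_class=rt_class,
            is_decay_intron=is_decay, n_motifs=n_motifs, motif_in="intron" if is_decay else "",
            pa_status="pA+",
        ))

    for cls, n, prefix, targets, down in (
        ("ncRNA", config.n_ncrna, "ncRNA", roles["nc_targets"], roles["down_nc"]),
        ("intergenic", config.n_intergenic, "INT", roles["int_targets"], roles["down_int"]),
    ):
        for i in range(n):
            gid = f"{prefix}_{i + 1:03d}"
            is_target = i in targets
            log2fc = config.log2fc_up if is_target else (config.log2fc_down if i in down else 0.0)
            pa = "pA-" if rng.random() < config.pa_minus_fraction else "pA+"
            expr = (
                expression(config.expr_min, config.target_expr_max)
                if is_target
                else expression(config.expr_min, config.expr_max)
            )
            genes.append(dict(
                gene_id=gid, fclass=cls, exon_lens=[int(rng.integers(300, 1001))],
                intron_lens=[], expression=expr,
                affinity=config.target_affinity if is_target else 1.0,
                log2fc=log2fc, ir_category="unchanged", rt_class=0,
                is_decay_intron=False,
                n_motifs=int(rng.integers(1, 4)) if is_target else 0,
                motif_in="exon" if is_target else "", pa_status=pa,
            ))

    for cls, n, prefix in (("snRNA", config.n_snrna, "snRNA"), ("snoRNA", config.n_snorna, "snoRNA")):
        for i in range(n):
            genes.append(dict(
                gene_id=f"{prefix}_{i + 1:03d}", fclass=cls,
                exon_lens=[int(rng.integers(100, 301))], intron_lens=[],
                expression=expression(config.expr_min, config.expr_max),
                affinity=1.0, log2fc=0.0,
                ir_category="unchanged", rt_class=0, is_decay_intron=False,
                n_motifs=0, motif_in="", pa_status="pA+",
            ))
    return genes


def _place_genes(config: SimConfig, rng: np.random.Generator, roles: dict) -> list[dict]:
    genes = _gene_structures(config, rng, roles)
    order = rng.permutation(len(genes))
    genes = [genes[i] for i in order]

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    cursor = {c: int(rng.integers(config.min_gap, config.max_gap)) for c in chrom_names}
    ci = 0
    for g in genes:
        length = sum(g["exon_lens"]) + sum(g["intron_lens"])
        placed = False
        for _ in range(config.n_chrom):
            chrom = chrom_names[ci % config.n_chrom]
            if cursor[chrom] + length + config.min_gap < config.chrom_length:
                start = cursor[chrom]
                g["chrom"], g["start"] = chrom, start
                g["strand"] = "+" if rng.random() < 0.5 else "-"
                exons = []
                pos = start
                for k, elen in enumerate(g["exon_lens"]):
                    exons.append((pos, pos + elen))
                    pos += elen
                    if k < len(g["intron_lens"]):
                        pos += g["intron_lens"][k]
                g["exons"] = exons
                g["end"] = pos
                cursor[chrom] = pos + int(rng.integers(config.min_gap, config.max_gap))
                placed = True
                ci += 1
                break
            ci += 1
        if not placed:
            raise ValueError(
                "genes do not fit on the chromosomes; increase chrom_length or n_chrom"
            )
    return genes


def _plant_motifs(seq: list[str], g: dict, rng: np.random.Generator) -> list[int]:
    """Write n_motifs sense-strand DSR copies into the gene; return genomic starts."""
    if g["motif_in"] == "intron":
        # first intron in genomic terms = gap after first exon
        s, e = g["exons"][0][1], g["exons"][1][0]
    else:
        lens = [b - a for a, b in g["exons"]]
        a, b = g["exons"][int(np.argmax(lens))]
        s, e = a, b
    margin = 10
    lo, hi = s + margin, e - margin - 6
    positions: list[int] = []
    attempts = 0
    while len(positions) < g["n_motifs"] and attempts < 200:
        attempts += 1
        p = int(rng.integers(lo, hi + 1))
        if all(abs(p - q) >= 10 for q in positions):
            positions.append(p)
    positions.sort()
    for p in positions:
        motif = "T" + DSR_VARIANT_MIDDLE[int(rng.integers(0, 3))] + "AAAC"
        if g["strand"] == "-":
            motif = reverse_complement(motif)
        seq[p : p + 6] = list(motif)
    return positions


def _build_truth(
    config: SimConfig,
    rng: np.random.Generator,
    genes: list[dict],
    annotation: GenomeAnnotation,
    genome: GenomeSequence,
) -> SimTruth:
    from .decay import scan_motif
    from .genomics import fetch_sequence

    rows = []
    for g in genes:
        ab_total = g["expression"]
        ab_pa = ab_total / config.pa_depletion if g["pa_status"] == "pA-" else ab_total
        decay_intron_id = (
            annotation.features[g["gene_id"]].intron_id(_first_intron_index(annotation.features[g["gene_id"]]))
            if g["is_decay_intron"]
            else ""
        )
        rows.append(dict(
            gene_id=g["gene_id"], fclass=g["fclass"], chrom=g["chrom"],
            strand=g["strand"], start=g["start"], end=g["end"],
            expression=g["expression"], abundance_total=ab_total,
            abundance_polyA=ab_pa, pa_status=g["pa_status"],
            affinity=g["affinity"], log2fc=g["log2fc"],
            ir_category=g["ir_category"], rt_class=g["rt_class"],
            is_decay_intron=bool(g["is_decay_intron"]),
            decay_intron_id=decay_intron_id,
            n_motifs=g["n_motifs"], motif_positions=list(g["motif_positions"]),
        ))
    df = pd.DataFrame(rows).set_index("gene_id", drop=False)

    intron_hits: dict[str, int] = {}
    for intron_id, _gene, intron in annotation.iter_introns():
        seq = fetch_sequence(genome, intron)
        intron_hits[intron_id] = len(scan_motif(seq, "TNAAAC"))
    return SimTruth(genes=df, intron_motif_counts=intron_hits)


def _first_intron_index(feature: Feature) -> int:
    """Index (transcript order) of the genomically first intron."""
    first = min(range(len(feature.introns)), key=lambda i: feature.introns[i].start)
    return first


# ---------------------------------------------------------------------------
# CRAC reads

def simulate_crac_reads(
    genome: GenomeSequence,
    annotation: GenomeAnnotation,
    truth: SimTruth,
    config: SimConfig,
) -> AlignmentSet:
    """Simulate a CRAC library.

    Per-gene read rate is proportional to affinity x expression.  For
    motif-carrying genes read starts are Normal(motif, sigma) truncated to
    the feature; for everything else reads are uniform over exons.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    g = truth.genes
    weights = (g["affinity"] * g["expression"]).to_numpy(float)
    counts = rng.multinomial(config.crac_depth, weights / weights.sum())

    rl = config.crac_read_length
    frames = []
    for (gid, row), n in zip(g.iterrows(), counts):
        if n == 0:
            continue
        feat = annotation.features[gid]
        lo, hi = feat.start, max(feat.start, feat.end - rl)
        motifs = row["motif_positions"]
        if len(motifs) > 0:
            centers = np.asarray(motifs, float)[rng.integers(0, len(motifs), size=n)] + 3.0
            starts = rng.normal(centers - rl / 2.0, config.motif_sigma)
            starts = np.clip(np.rint(starts), lo, hi).astype(int)
        else:
            starts = _uniform_exonic_starts(feat, n, rl, rng)
        frames.append(pd.DataFrame({
            "chrom": feat.chrom, "start": starts, "end": starts + rl, "strand": feat.strand,
        }))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort").reset_index(drop=True)
    return AlignmentSet(df, total_mapped=len(df), library_id="crac")


def _uniform_exonic_starts(
    feat: Feature, n: int, read_len: int, rng: np.random.Generator
) -> np.ndarray:
    exons = feat.exons_genomic()
    lens = np.array([e.length for e in exons], float)
    which = rng.integers(0, len(exons), size=n) if len(exons) > 1 else np.zeros(n, int)
    if len(exons) > 1:
        which = rng.choice(len(exons), size=n, p=lens / lens.sum())
    starts = np.empty(n, dtype=int)
    for i, e in enumerate(exons):
        m = which == i
        k = int(m.sum())
        if k == 0:
            continue
        hi = max(e.start + 1, e.end - read_len)
        starts[m] = rng.integers(e.start, hi, size=k)
    return starts


# ---------------------------------------------------------------------------
# RNA-seq reads

def simulate_rnaseq(
    annotation: GenomeAnnotation,
    truth: SimTruth,
    condition: str,
    config: SimConfig,
) -> tuple[list[AlignmentSet], pd.DataFrame]:
    """Simulate replicate RNA-seq libraries for one condition.

    Returns the per-replicate read sets and a gene x replicate count
    matrix (gene-body counts).  Counts are NB(mu, dispersion) with
    variance mu + dispersion * mu^2; mutant means are scaled by
    2**log2fc for planted genes.  Reads fall uniformly over exons except
    that intron-containing genes place an ``unspliced`` fraction of reads
    uniformly over the unspliced span (yielding intronic and
    junction-spanning coverage), elevated in the mutant for
    splicing-defect genes.  Readthrough genes add class-specific reads in
    the window downstream of the 3' end.
    """
    if condition not in ("WT", "mutant"):
        raise ValueError(f"unknown condition {condition!r}")
    cond_code = 2 if condition == "WT" else 3
    g = truth.genes
    base = g["expression"].to_numpy(float)
    scale = np.power(2.0, g["log2fc"].to_numpy(float)) if condition == "mutant" else 1.0
    mu = config.rnaseq_depth * base * scale / base.sum()
    mu_base = config.rnaseq_depth * base / base.sum()

    rl = config.read_length
    nb_n = 1.0 / config.nb_dispersion
    rt_level = config.rt_signal_mut if condition == "mutant" else config.rt_signal_wt

    libraries: list[AlignmentSet] = []
    count_cols = {}
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), cond_code, rep]))
        counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
        frames = []
        for (gid, row), c, mb in zip(g.iterrows(), counts, mu_base):
            feat = annotation.features[gid]
            starts_parts = []
            if c > 0:
                if feat.introns:
                    f_un = config.ir_baseline_unspliced
                    if condition == "mutant" and row["ir_category"] == "splicing_defect":
                        f_un = config.ir_defect_unspliced
                    n_pre = rng.binomial(c, f_un)
                else:
                    n_pre = 0
                n_mat = c - n_pre
                if n_mat > 0:
                    starts_parts.append(_uniform_exonic_starts(feat, n_mat, rl, rng))
                if n_pre > 0:
                    hi = max(feat.start + 1, feat.end - rl)
                    starts_parts.append(rng.integers(feat.start, hi, size=n_pre))
            if row["rt_class"] > 0:
                n_ds = rng.poisson(rt_level * mb)
                if n_ds > 0:
                    if feat.strand == "+":
                        lo, hi = feat.end, feat.end + config.rt_length - rl
                    else:
                        lo, hi = feat.start - config.rt_length, feat.start - rl
                    starts_parts.append(rng.integers(lo, max(lo + 1, hi), size=n_ds))
            if not starts_parts:
                continue
            starts = np.concatenate(starts_parts)
            frames.append(pd.DataFrame({
                "chrom": feat.chrom, "start": starts, "end": starts + rl,
                "strand": feat.strand,
            }))
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort").reset_index(drop=True)
        lib_id = f"{condition}_rep{rep + 1}"
        libraries.append(AlignmentSet(df, total_mapped=len(df), library_id=lib_id))
        count_cols[lib_id] = counts
    count_matrix = pd.DataFrame(count_cols, index=g.index)
    return libraries, count_matrix


def abundance_tables(truth: SimTruth) -> tuple[pd.Series, pd.Series]:
    """(oligo-dT abundance, total abundance) per feature, from truth."""
    g = truth.genes
    return g["abundance_polyA"].rename("abundance"), g["abundance_total"].rename("abundance")
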