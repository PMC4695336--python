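"""End-to-end orchestration on synthetic data plus evaluation helpers.

``run_pipeline`` chains simulate -> binding -> DE -> intron retention ->
readthrough -> decay-intron calling, writes every stage's table under an
output directory together with a run manifest, and returns the in-memory
results.  ``evaluate_run`` scores the stage outputs against the planted
truth (motif recovery, DE sensitivity, IR/readthrough accuracy,
decay-intron precision/recall).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import (
    Cluster,
    EnrichmentRecord,
    FeatureCounts,
    KmerStat,
    PolyAConfig,
    assign_reads_to_features,
    call_clusters,
    classify_polyA,
    compute_enrichment,
    intronic_binding_fraction,
    kmer_enrichment,
)
from .decay import DecayIntronCall, call_decay_introns, intron_motif_census, scan_interval_motifs
from .diffexpr import CountMatrix, classify_de, nb_wald_test, tally_classes
from .genomics import (
    AlignmentSet,
    GenomeAnnotation,
    GenomeSequence,
    write_bed6,
    write_fasta,
    write_gff3,
)
from .readthrough import ReadthroughRecord, classify_readthrough, downstream_signal
from .simulate import SimConfig, SimTruth, abundance_tables, simulate_crac_reads, simulate_genome, simulate_rnaseq
from .splicing import IRCall, classify_ir_change, compute_intron_metrics

log = logging.getLogger(__name__)

DSR_REGEX = re.compile("^T[TCG]AAAC$")


@dataclass
class PipelineResult:
    genome: GenomeSequence
    annotation: GenomeAnnotation
    truth: SimTruth
    crac: AlignmentSet
    crac_counts: FeatureCounts
    clusters: list[Cluster]
    kmers: list[KmerStat]
    enrichment: list[EnrichmentRecord]
    pa_status: dict[str, str]
    count_matrix: CountMatrix
    de: pd.DataFrame
    tally: pd.DataFrame
    ir_calls: dict[str, IRCall]
    readthrough: list[ReadthroughRecord]
    decay_calls: list[DecayIntronCall]
    binding_fractions: dict[str, float] = field(default_factory=dict)
    rnaseq_wt: AlignmentSet | None = None
    rnaseq_mut: AlignmentSet | None = None


def run_pipeline(
    config: SimConfig,
    outdir: str | Path | None = None,
    min_height: int = 5,
    min_length: int = 12,
    k: int = 6,
    n_shuffles: int = 100,
    fold: float = 1.5,
    alpha: float = 0.05,
    window_nt: int = 300,
    f_min: float = 0.5,
) -> PipelineResult:
    """Run the full synthetic analysis; write stage outputs if outdir given."""
    log.info("simulating genome (seed=%d)", config.seed)
    genome, annotation, truth = simulate_genome(config)
    crac = simulate_crac_reads(genome, annotation, truth, config)
    wt_libs, wt_counts = simulate_rnaseq(annotation, truth, "WT", config)
    mut_libs, mut_counts = simulate_rnaseq(annotation, truth, "mutant", config)

    # binding stage
    crac_counts = assign_reads_to_features(crac, annotation)
    clusters = call_clusters(crac, genome, min_height=min_height, min_length=min_length)
    kmers = kmer_enrichment(clusters, k=k, n_shuffles=n_shuffles, seed=config.seed)
    ab_pa, ab_total = abundance_tables(truth)
    enrichment = compute_enrichment(crac_counts.sense, ab_total, annotation)
    pa_status = classify_polyA(ab_pa, ab_total, PolyAConfig())
    for rec in enrichment:
        rec.pA = pa_status.get(rec.feature_id, "NA")

    # DE stage
    counts = pd.concat([wt_counts, mut_counts], axis=1)
    conditions = {c: ("WT" if c.startswith("WT") else "mutant") for c in counts.columns}
    cm = CountMatrix(counts, conditions)
    de = classify_de(nb_wald_test(cm), fold=fold, alpha=alpha)
    fclasses = truth.genes["fclass"].to_dict()
    tally = tally_classes(de["call"].to_dict(), fclasses)

    # intron retention (replicates pooled per condition)
    wt_pool = AlignmentSet.concat(wt_libs, "WT_pooled")
    mut_pool = AlignmentSet.concat(mut_libs, "mutant_pooled")
    ir_calls: dict[str, IRCall] = {}
    for feat in annotation:
        if not feat.introns:
            continue
        for m_wt, m_mut in zip(
            compute_intron_metrics(wt_pool, feat), compute_intron_metrics(mut_pool, feat)
        ):
            ir_calls[m_wt.intron_id] = classify_ir_change(m_wt, m_mut)

    # readthrough
    readthrough: list[ReadthroughRecord] = []
    for feat in annotation:
        rpm_wt, window = downstream_signal(wt_pool, feat, annotation, window_nt)
        rpm_mut, _ = downstream_signal(mut_pool, feat, annotation, window_nt)
        body_call = de.loc[feat.id, "call"] if feat.id in de.index else "unchanged"
        readthrough.append(
            classify_readthrough(feat.id, rpm_wt, rpm_mut, body_call, window)
        )

    # decay-intron caller
    binding_fractions: dict[str, float] = {}
    motif_counts: dict[str, int] = {}
    for intron_id, feat, intron in annotation.iter_introns():
        binding_fractions[intron_id] = intronic_binding_fraction(feat, crac)
        motif_counts[intron_id] = len(scan_interval_motifs(genome, intron, "DSR"))
    decay_calls = call_decay_introns(
        binding_fractions, motif_counts, {k: v.call for k, v in ir_calls.items()}, f_min=f_min
    )

    result = PipelineResult(
        genome=genome, annotation=annotation, truth=truth, crac=crac,
        crac_counts=crac_counts, clusters=clusters, kmers=kmers,
        enrichment=enrichment, pa_status=pa_status, count_matrix=cm, de=de,
        tally=tally, ir_calls=ir_calls, readthrough=readthrough,
        decay_calls=decay_calls, binding_fractions=binding_fractions,
        rnaseq_wt=wt_pool, rnaseq_mut=mut_pool,
    )
    if outdir is not None:
        write_outputs(result, config, Path(outdir), wt_libs, mut_libs)
    return result


def write_outputs(
    result: PipelineResult,
    config: SimConfig,
    outdir: Path,
    wt_libs: list[AlignmentSet],
    mut_libs: list[AlignmentSet],
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome, outdir / "genome.fa")
    write_gff3(result.annotation, outdir / "annotation.gff3")
    result.truth.to_json(outdir / "truth.json")
    write_bed6(result.crac, outdir / "crac.bed")
    for lib in wt_libs + mut_libs:
        write_bed6(lib, outdir / f"rnaseq_{lib.library_id}.bed")

    pd.DataFrame(
        [(fid, n, result.crac_counts.antisense.get(fid, 0)) for fid, n in result.crac_counts.sense.items()],
        columns=["feature_id", "crac_count", "antisense_count"],
    ).to_csv(outdir / "crac_counts.tsv", sep="\t", index=False)

    with open(outdir / "clusters.bed", "w") as fh:
        for i, c in enumerate(result.clusters):
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\tcluster{i}"
                f"\t{c.height}\t{c.interval.strand}\n"
            )
    pd.DataFrame([dataclasses.asdict(s) for s in result.kmers]).to_csv(
        outdir / "kmers.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(r) for r in result.enrichment]).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False
    )
    result.count_matrix.to_tsv(outdir / "counts.tsv")
    result.de.to_csv(outdir / "de.tsv", sep="\t")
    result.tally.to_csv(outdir / "de_tally.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in result.ir_calls.values()]).to_csv(
        outdir / "ir_calls.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            dict(
                gene_id=r.gene_id,
                window=f"{r.window.chrom}:{r.window.start}-{r.window.end}" if r.window else "NA",
                rpm_wt=r.downstream_rpm_wt, rpm_mut=r.downstream_rpm_mut,
                fold=r.downstream_fold, body_call=r.body_call, rt_class=r.rt_class,
            )
            for r in result.readthrough
        ]
    ).to_csv(outdir / "readthrough.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            dict(
                intron_id=c.intron_id, intronic_fraction=c.intronic_fraction,
                motif_count=c.motif_count, ir_call=c.ir_call, verdict=c.verdict,
                ev_binding=c.evidence.get("binding"), ev_motif=c.evidence.get("motif"),
                ev_ir=c.evidence.get("ir"),
            )
            for c in result.decay_calls
        ]
    ).to_csv(outdir / "decay_introns.tsv", sep="\t", index=False)

    census = intron_motif_census(result.annotation, result.genome)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "report": {
            "n_clusters": len(result.clusters),
            "top_kmers": [s.kmer for s in result.kmers[:5]],
            "intron_motif_census": dataclasses.asdict(census) | {"fraction": census.fraction},
            "n_decay_verdicts": sum(c.verdict for c in result.decay_calls),
            "intergenic_read_count": result.crac_counts.intergenic,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# evaluation against planted truth

def top_kmer_is_dsr(kmers: list[KmerStat]) -> bool:
    return bool(kmers) and DSR_REGEX.match(kmers[0].kmer) is not None


def evaluate_run(result: PipelineResult) -> dict[str, float]:
    """Score stage outputs against the planted truth."""
    truth = result.truth.genes
    out: dict[str, float] = {}

    out["top_kmer_is_motif"] = float(top_kmer_is_dsr(result.kmers))

    # DE sensitivity / FDR over well-measured genes
    de = result.de
    mu = de[["mean_wt", "mean_mut"]].min(axis=1)
    strong = truth.index[(truth["log2fc"].abs() >= 2) & (de.loc[truth.index, "mean_wt"] >= 50)]
    if len(strong):
        correct = sum(
            (de.loc[g, "call"] == ("up" if truth.loc[g, "log2fc"] > 0 else "down"))
            for g in strong
        )
        out["de_sensitivity"] = correct / len(strong)
    disc = de.index[(de["q"] < 0.05) & (de["call"] != "unchanged")]
    if len(disc):
        fp = sum(truth.loc[g, "log2fc"] == 0 for g in disc)
        out["de_fdr"] = fp / len(disc)

    # IR category accuracy over intron-containing genes (first intron)
    n, ok = 0, 0
    for gid, row in truth.iterrows():
        feat = result.annotation.features[gid]
        if not feat.introns:
            continue
        iid = feat.intron_id(0)
        if iid not in result.ir_calls:
            continue
        n += 1
        ok += int(result.ir_calls[iid].call == row["ir_category"])
    if n:
        out["ir_accuracy"] = ok / n
        out["ir_n"] = n

    # readthrough class accuracy (over genes with a usable window)
    n, ok = 0, 0
    for rec in result.readthrough:
        if rec.flagged:
            continue
        n += 1
        ok += int(rec.rt_class == int(truth.loc[rec.gene_id, "rt_class"]))
    if n:
        out["readthrough_accuracy"] = ok / n
        out["readthrough_n"] = n

    # decay-intron precision/recall against planted decay introns
    truth_pos = set(truth.loc[truth["is_decay_intron"], "decay_intron_id"])
    called = {c.intron_id for c in result.decay_calls if c.verdict}
    tp = len(called & truth_pos)
    out["decay_precision"] = tp / len(called) if called else float("nan")
    out["decay_recall"] = tp / len(truth_pos) if truth_pos else float("nan")

    # pA classification agreement
    truth_pa = truth["pa_status"]
    pred = pd.Series(result.pa_status)
    shared = truth_pa.index.intersection(pred.index)
    out["pa_agreement"] = float((pred[shared] == truth_pa[shared]).mean())

    # enrichment tracks planted affinity
    enr = pd.DataFrame(
        [(r.feature_id, r.enrichment) for r in result.enrichment], columns=["gene_id", "enr"]
    ).set_index("gene_id")["enr"]
    shared = truth.index.intersection(enr.index[np.isfinite(enr)])
    from scipy.stats import spearmanr

    out["enrichment_affinity_spearman"] = float(
        spearmanr(enr[shared], truth.loc[shared, "affinity"]).statistic
    )
    return out
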