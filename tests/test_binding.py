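"""CRAC binding: assignment, clusters, k-mers, enrichment, pA, intronic fraction."""

import math

import numpy as np
import pandas as pd
import pytest

from exotarget.binding import (
    Cluster,
    PolyAConfig,
    assign_reads_to_features,
    call_clusters,
    classify_polyA,
    compute_enrichment,
    intronic_binding_fraction,
    kmer_enrichment,
)
from exotarget.genomics import (
    AlignmentSet,
    Feature,
    GenomeAnnotation,
    GenomeSequence,
    GenomicInterval,
)


def _aln(rows, total=None, lib="t"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return AlignmentSet(df, total if total is not None else len(df), lib)


def _brute_force_assign(reads, feats):
    """Independent per-read maximal-overlap assignment."""
    sense: dict = {f.id: 0 for f in feats}
    anti: dict = {f.id: 0 for f in feats}
    inter = 0
    flip = {"+": "-", "-": "+"}
    for chrom, s, e, strand in reads:
        def best(want_strand):
            cands = []
            for f in feats:
                if f.chrom != chrom or f.strand != want_strand:
                    continue
                ov = min(e, f.end) - max(s, f.start)
                if ov > 0:
                    cands.append((-ov, f.interval.length, f.id))
            return min(cands)[2] if cands else None
        b = best(strand)
        if b is not None:
            sense[b] += 1
            continue
        b = best(flip[strand])
        if b is not None:
            anti[b] += 1
        else:
            inter += 1
    return sense, anti, inter


class TestAssignment:
    def test_read_inside_single_gene(self):
        f = Feature.build("g", "mRNA", "c", "+", [(100, 500)])
        ann = GenomeAnnotation([f], {"c": 1000})
        counts = assign_reads_to_features(_aln([("c", 200, 240, "+")]), ann)
        assert counts.sense["g"] == 1 and counts.intergenic == 0

    def test_read_overlapping_nothing_is_intergenic(self):
        f = Feature.build("g", "mRNA", "c", "+", [(100, 500)])
        ann = GenomeAnnotation([f], {"c": 1000})
        counts = assign_reads_to_features(_aln([("c", 600, 640, "+")]), ann)
        assert counts.intergenic == 1

    def test_antisense_only_overlap_tallied_separately(self):
        f = Feature.build("g", "mRNA", "c", "+", [(100, 500)])
        ann = GenomeAnnotation([f], {"c": 1000})
        counts = assign_reads_to_features(_aln([("c", 200, 240, "-")]), ann)
        assert counts.antisense["g"] == 1 and counts.sense["g"] == 0

    def test_tie_break_prefers_smaller_feature(self):
        broad = Feature.build("broad", "mRNA", "c", "+", [(0, 1000)])
        # same overlap with the read, but smaller feature wins
        narrow = Feature.build("narrow", "ncRNA", "c", "+", [(100, 200)])
        ann = GenomeAnnotation([broad, narrow], {"c": 1000})
        counts = assign_reads_to_features(_aln([("c", 120, 160, "+")]), ann)
        assert counts.sense["narrow"] == 1 and counts.sense["broad"] == 0

    def test_matches_brute_force_on_random_reads(self):
        rng = np.random.default_rng(42)
        feats = []
        pos = 0
        for i in range(20):
            pos += int(rng.integers(50, 200))
            ln = int(rng.integers(100, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(Feature.build(f"g{i}", "mRNA", "c", strand, [(pos, pos + ln)]))
            pos += ln
        ann = GenomeAnnotation(feats, {"c": pos + 1000})
        reads = [
            ("c", s, s + 40, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, pos, 500)
        ]
        counts = assign_reads_to_features(_aln(reads), ann)
        sense, anti, inter = _brute_force_assign(reads, feats)
        assert counts.sense == sense
        assert counts.antisense == anti
        assert counts.intergenic == inter

    def test_conservation_invariant(self, default_run):
        c = default_run.crac_counts
        assert c.total_assigned() == c.n_reads


class TestClusters:
    @pytest.fixture()
    def flat_genome(self):
        return GenomeSequence({"c": "A" * 2000})

    def test_stacked_reads_form_one_cluster(self, flat_genome):
        reads = _aln([("c", 100, 140, "+")] * 10)
        cl = call_clusters(reads, flat_genome, min_height=5)
        assert len(cl) == 1
        assert (cl[0].interval.start, cl[0].interval.end, cl[0].height) == (100, 140, 10)
        assert cl[0].n_reads == 10

    def test_below_min_height_no_cluster(self, flat_genome):
        reads = _aln([("c", 100, 140, "+")] * 4)
        assert call_clusters(reads, flat_genome, min_height=5) == []

    def test_short_cluster_discarded(self, flat_genome):
        reads = _aln([("c", 100, 110, "+")] * 8)
        assert call_clusters(reads, flat_genome, min_height=5, min_length=12) == []

    def test_matches_per_base_coverage_oracle(self, flat_genome):
        rng = np.random.default_rng(3)
        for trial in range(20):
            starts = rng.integers(0, 1800, 200)
            reads = _aln([("c", int(s), int(s) + 30, "+") for s in starts])
            got = call_clusters(reads, flat_genome, min_height=5, min_length=12, merge_gap=3)
            cov = np.zeros(2000, dtype=int)
            for s in starts:
                cov[s : s + 30] += 1
            above = cov >= 5
            # brute-force runs + merge + length filter
            runs = []
            i = 0
            while i < 2000:
                if above[i]:
                    j = i
                    while j < 2000 and above[j]:
                        j += 1
                    runs.append([i, j])
                    i = j
                else:
                    i += 1
            merged = []
            for r in runs:
                if merged and r[0] - merged[-1][1] < 3:
                    merged[-1][1] = r[1]
                else:
                    merged.append(r)
            expect = [(s, e) for s, e in merged if e - s >= 12]
            assert [(c.interval.start, c.interval.end) for c in got] == expect
            for c in got:
                assert c.height == cov[c.interval.start : c.interval.end].max()


class TestKmerEnrichment:
    def _clusters(self, seqs):
        return [
            Cluster(GenomicInterval("c", 0, len(s), "+"), 10, 10, s) for s in seqs
        ]

    def test_degenerate_composition_gives_undefined_z_and_p_one(self):
        stats = kmer_enrichment(self._clusters(["AAAAAAAA"]), k=6, n_shuffles=20, seed=0)
        rec = next(s for s in stats if s.kmer == "AAAAAA")
        assert math.isnan(rec.z)
        assert rec.p_emp == 1.0

    def test_all_clusters_too_short_raises(self):
        with pytest.raises(ValueError):
            kmer_enrichment(self._clusters(["ACGT"]), k=6)

    def test_planted_hexamer_ranks_first(self, rng):
        seqs = []
        for _ in range(20):
            s = "".join("ACGT"[b] for b in rng.integers(0, 4, 40))
            seqs.append(s[:10] + "TTAAAC" + s[16:30] + "TTAAAC" + s[36:])
        stats = kmer_enrichment(self._clusters(seqs), k=6, n_shuffles=100, seed=1)
        assert stats[0].kmer == "TTAAAC"
        assert stats[0].z > 10
        # empirical p sits at the +1/+1 floor: no shuffle reaches the observed count
        assert stats[0].p_emp == pytest.approx(1 / 101)

    def test_no_signal_in_random_clusters(self):
        """Min q over hexamers exceeds 0.05 for nearly all seeds under the null."""
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 30)) for _ in range(20)]
            stats = kmer_enrichment(self._clusters(seqs), k=6, n_shuffles=100, seed=seed)
            ok += min(s.q for s in stats) > 0.05
        assert ok >= 95

    def test_ranking_stable_under_cluster_duplication(self, rng):
        seqs = []
        for _ in range(10):
            s = "".join("ACGT"[b] for b in rng.integers(0, 4, 40))
            seqs.append(s[:12] + "TCAAAC" + s[18:])
        top1 = kmer_enrichment(self._clusters(seqs), n_shuffles=100, seed=5)[0].kmer
        top2 = kmer_enrichment(self._clusters(seqs * 2), n_shuffles=100, seed=5)[0].kmer
        assert top1 == top2 == "TCAAAC"

    def test_n_bases_never_match(self):
        stats = kmer_enrichment(self._clusters(["TTAAACNNNNNNTTAAAC"]), n_shuffles=10, seed=0)
        rec = next(s for s in stats if s.kmer == "TTAAAC")
        assert rec.observed == 2  # windows containing N contribute nothing


class TestEnrichment:
    def _ann(self):
        f = Feature.build("g1", "mRNA", "c", "+", [(0, 100)])
        g = Feature.build("g2", "ncRNA", "c", "+", [(200, 300)])
        return GenomeAnnotation([f, g], {"c": 1000})

    def test_formula_with_pseudocount(self):
        recs = compute_enrichment({"g1": 100}, pd.Series({"g1": 10.0}), self._ann())
        assert recs[0].enrichment == pytest.approx(100 / 10.1)

    def test_equal_abundance_preserves_count_ranking(self):
        counts = {"g1": 500, "g2": 50}
        ab = pd.Series({"g1": 7.0, "g2": 7.0})
        recs = compute_enrichment(counts, ab, self._ann())
        assert [r.feature_id for r in recs] == ["g1", "g2"]

    def test_missing_abundance_excluded_from_ranking(self):
        recs = compute_enrichment({"g1": 10, "g2": 99}, pd.Series({"g1": 1.0}), self._ann())
        assert math.isnan(recs[-1].enrichment) and recs[-1].feature_id == "g2"

    def test_enrichment_tracks_planted_affinity(self, default_run):
        from exotarget.pipeline import evaluate_run

        ev = evaluate_run(default_run)
        assert ev["enrichment_affinity_spearman"] > 0.5


class TestPolyA:
    def test_no_depletion_is_pa_plus(self):
        status = classify_polyA(pd.Series({"a": 5.0}), pd.Series({"a": 5.0}))
        assert status["a"] == "pA+"

    def test_twentyfold_depletion_is_pa_minus(self):
        ab_pa = pd.Series({"a": 1.0, "b": 20.0, "c": 30.0})
        ab_t = pd.Series({"a": 20.0, "b": 20.0, "c": 30.0})
        assert classify_polyA(ab_pa, ab_t)["a"] == "pA-"

    def test_missing_feature_is_na(self):
        status = classify_polyA(pd.Series({"a": 1.0}), pd.Series({"a": 1.0, "b": 2.0}))
        assert status["b"] == "NA"

    def test_scale_invariance(self, rng):
        ids = [f"f{i}" for i in range(50)]
        pa = pd.Series(rng.uniform(0.1, 100, 50), index=ids)
        tot = pd.Series(rng.uniform(0.1, 100, 50), index=ids)
        base = classify_polyA(pa, tot)
        assert classify_polyA(pa * 37.0, tot) == base
        assert classify_polyA(pa, tot * 0.01) == base

    def test_enrichment_direction_flag(self):
        ab_pa = pd.Series({"a": 100.0, "b": 1.0, "c": 1.0})
        ab_t = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        status = classify_polyA(ab_pa, ab_t, PolyAConfig(direction="enrichment"))
        assert status["a"] == "pA+" and status["b"] == "pA-"

    def test_planted_classes_recovered(self, default_run):
        from exotarget.pipeline import evaluate_run

        assert evaluate_run(default_run)["pa_agreement"] == 1.0


class TestIntronicFraction:
    def _feat(self):
        return Feature.build("g", "mRNA", "c", "+", [(0, 100), (200, 300)])

    def test_all_reads_intronic(self):
        reads = _aln([("c", 140, 160, "+")] * 10)
        assert intronic_binding_fraction(self._feat(), reads) == 1.0

    def test_half_intronic(self):
        reads = _aln([("c", 140, 160, "+")] * 5 + [("c", 40, 60, "+")] * 5)
        assert intronic_binding_fraction(self._feat(), reads) == 0.5

    def test_no_reads_is_nan(self):
        reads = _aln([("c", 500, 540, "+")])
        assert math.isnan(intronic_binding_fraction(self._feat(), reads))

    def test_intronless_feature_raises(self):
        f = Feature.build("g", "mRNA", "c", "+", [(0, 100)])
        with pytest.raises(ValueError):
            intronic_binding_fraction(f, _aln([("c", 10, 30, "+")]))

    def test_matches_midpoint_oracle(self, rng):
        feat = self._feat()
        starts = rng.integers(0, 320, 300)
        reads = _aln([("c", int(s), int(s) + 20, "+") for s in starts])
        got = intronic_binding_fraction(feat, reads)
        mids = [s + 10 for s in starts]
        in_feat = [m for m in mids if 0 <= m < 300]
        in_intron = [m for m in in_feat if 100 <= m < 200]
        assert got == pytest.approx(len(in_intron) / len(in_feat))
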