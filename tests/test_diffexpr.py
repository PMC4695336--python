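"""NB differential expression, BH, tallies and gene-set enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exotarget.diffexpr import (
    CountMatrix,
    bh_adjust,
    classify_de,
    estimate_size_factors,
    hypergeom_enrichment,
    nb_wald_test,
    round_half_up_pct,
    tally_classes,
)


def _cm(counts: pd.DataFrame) -> CountMatrix:
    cond = {c: ("WT" if c.startswith("wt") else "mutant") for c in counts.columns}
    return CountMatrix(counts, cond)


def _null_counts(rng, n_genes=2000, disp=0.05):
    mu = np.exp(rng.uniform(np.log(20), np.log(1000), n_genes))
    n = 1 / disp
    cols = {}
    for i in range(3):
        cols[f"wt{i}"] = rng.negative_binomial(n, n / (n + mu))
    for i in range(3):
        cols[f"mut{i}"] = rng.negative_binomial(n, n / (n + mu))
    return pd.DataFrame(cols)


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(estimate_size_factors(counts), [1.0, 1.0])

    def test_doubled_sample(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = estimate_size_factors(counts)
        assert f["a"] == pytest.approx(1 / math.sqrt(2))
        assert f["b"] == pytest.approx(math.sqrt(2))

    def test_recovers_true_scaling_on_nb_data(self, rng):
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 3000))
        true = np.array([0.5, 1.0, 2.0, 1.5])
        cols = {
            f"s{i}": rng.negative_binomial(20, 20 / (20 + mu * t))
            for i, t in enumerate(true)
        }
        f = estimate_size_factors(pd.DataFrame(cols)).to_numpy()
        expect = true / np.exp(np.log(true).mean())
        assert np.allclose(f, expect, rtol=0.05)

    def test_fallback_when_no_common_nonzero(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        f = estimate_size_factors(counts)
        assert np.allclose(f, [1.0, 1.0])


class TestBH:
    def test_forced_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 100)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        # q_(i) = min_{j>=i} m * p_(j) / j
        for i in range(m):
            ps = p[order]
            expect = min(m * ps[j] / (j + 1) for j in range(i, m))
            assert q[order[i]] == pytest.approx(min(expect, 1.0))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        assert (q <= 1).all() and (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestWaldTest:
    def test_equal_means_give_null_result(self):
        counts = pd.DataFrame({
            "wt1": [100] * 10, "wt2": [105] * 10, "wt3": [95] * 10,
            "mut1": [100] * 10, "mut2": [98] * 10, "mut3": [102] * 10,
        })
        res = nb_wald_test(_cm(counts))
        assert np.abs(res["log2fc"]).max() < 0.2
        assert (res["p"] > 0.2).all()

    def test_all_zero_condition_flagged_p_one(self):
        counts = pd.DataFrame({
            "wt1": [0, 50], "wt2": [0, 60], "wt3": [0, 40],
            "mut1": [80, 55], "mut2": [90, 45], "mut3": [85, 50],
        })
        res = nb_wald_test(_cm(counts))
        assert res["flagged"].iloc[0] and res["p"].iloc[0] == 1.0
        assert not res["flagged"].iloc[1]

    def test_label_swap_negates_log2fc_keeps_p(self, rng):
        counts = _null_counts(rng, n_genes=300)
        res = nb_wald_test(_cm(counts))
        swapped = counts.rename(columns=lambda c: c.replace("wt", "xx").replace("mut", "wt").replace("xx", "mut"))
        res2 = nb_wald_test(_cm(swapped))
        assert np.allclose(res["log2fc"], -res2["log2fc"], atol=1e-9)
        assert np.allclose(res["p"], res2["p"], atol=1e-9)

    def test_type_one_error_calibrated(self):
        """Null NB data: fraction p<0.05 within [0.03, 0.07] (3v3, 2000 genes)."""
        rng = np.random.default_rng(2024)
        frac = (nb_wald_test(_cm(_null_counts(rng)))["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_pooled_dispersion_mode_also_calibrated(self):
        rng = np.random.default_rng(77)
        res = nb_wald_test(_cm(_null_counts(rng)), dispersion_mode="pooled")
        assert 0.02 <= (res["p"] < 0.05).mean() <= 0.08

    def test_power_on_planted_fourfold(self, rng):
        n, n_up = 1000, 100
        mu = np.full(n, 100.0)
        fc = np.ones(n)
        fc[:n_up] = 4.0
        nb = 1 / 0.05
        cols = {f"wt{i}": rng.negative_binomial(nb, nb / (nb + mu)) for i in range(3)}
        cols |= {f"mut{i}": rng.negative_binomial(nb, nb / (nb + mu * fc)) for i in range(3)}
        res = classify_de(nb_wald_test(_cm(pd.DataFrame(cols))))
        assert (res["call"].iloc[:n_up] == "up").mean() >= 0.95

    def test_sensitivity_and_fdr_on_default_synthetic_set(self, default_run):
        """Planted |log2FC|>=2 genes at mu>=50: sensitivity >=0.9, FDR <=0.1 at q<0.05."""
        from exotarget.pipeline import evaluate_run

        ev = evaluate_run(default_run)
        assert ev["de_sensitivity"] >= 0.9
        assert ev["de_fdr"] <= 0.1


class TestClassifyDE:
    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [
            (1.0, 0.001, "up"),
            (1.0, 0.2, "unchanged"),
            (-1.0, 0.001, "down"),
            # fold exactly 1.5: strict > excludes it
            (math.log2(1.5), 0.01, "unchanged"),
            (-math.log2(1.5), 0.01, "unchanged"),
        ],
    )
    def test_call_rule(self, log2fc, p, expected):
        res = pd.DataFrame({"log2fc": [log2fc], "p": [p]})
        assert classify_de(res)["call"].iloc[0] == expected


class TestTally:
    def test_downregulated_class_percentages(self):
        calls = {}
        fcls = {}
        i = 0
        for fclass, n in [("ncRNA", 159), ("mRNA", 147), ("intergenic", 135), ("snoRNA", 4)]:
            for _ in range(n):
                calls[f"g{i}"] = "down"
                fcls[f"g{i}"] = fclass
                i += 1
        t = tally_classes(calls, fcls).set_index("fclass")
        assert t.loc["ncRNA", "pct"] == 36
        assert t.loc["mRNA", "pct"] == 33
        assert t.loc["intergenic", "pct"] == 30
        assert t["count"].sum() == 445

    def test_upregulated_class_percentages(self):
        calls = {}
        fcls = {}
        i = 0
        for fclass, n in [("intergenic", 1153), ("mRNA", 221), ("ncRNA", 210), ("tRNA", 26)]:
            for _ in range(n):
                calls[f"g{i}"] = "up"
                fcls[f"g{i}"] = fclass
                i += 1
        t = tally_classes(calls, fcls).set_index("fclass")
        assert t.loc["intergenic", "pct"] == 72
        assert t.loc["mRNA", "pct"] == 14
        assert t.loc["ncRNA", "pct"] == 13

    def test_single_class_is_hundred_percent(self):
        t = tally_classes({"a": "up", "b": "up"}, {"a": "mRNA", "b": "mRNA"})
        assert t["pct"].tolist() == [100]

    def test_round_half_up(self):
        assert round_half_up_pct(1, 8) == 13  # 12.5 -> 13
        assert round_half_up_pct(135, 445) == 30


class TestHypergeom:
    def test_small_case_matches_enumeration(self):
        # N=10, K=5, n=4: P(overlap=4) by exhaustive draws = C(5,4)/C(10,4)
        res = hypergeom_enrichment(
            [f"q{i}" for i in range(4)],
            [f"q{i}" for i in range(4)] + ["x"],
            [f"q{i}" for i in range(4)] + ["x"] + [f"u{i}" for i in range(5)],
        )
        assert res.k == 4 and res.K == 5 and res.n == 4 and res.N == 10
        assert res.p == pytest.approx(5 / 210)

    def test_empty_set_p_one(self):
        res = hypergeom_enrichment(["a"], [], ["a", "b", "c"])
        assert res.p == 1.0

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment([], [], [])

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            N = int(rng.integers(5, 16))
            universe = [f"u{i}" for i in range(N)]
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            gene_set = list(rng.choice(universe, K, replace=False))
            query = list(rng.choice(universe, n, replace=False))
            res = hypergeom_enrichment(query, gene_set, universe)
            k_obs = len(set(query) & set(gene_set))
            total = hits = 0
            for draw in itertools.combinations(universe, n):
                total += 1
                hits += len(set(draw) & set(gene_set)) >= k_obs
            assert res.p == pytest.approx(hits / total)
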