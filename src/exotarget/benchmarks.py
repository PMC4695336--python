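"""Repeatable benchmark computations on synthetic data.

These drive both the test suite and the reproduction script: motif
recovery across seeded simulations, NB-test calibration and power, and
truth-recovery scores for the full pipeline.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .binding import call_clusters, kmer_enrichment
from .diffexpr import CountMatrix, classify_de, nb_wald_test
from .pipeline import top_kmer_is_dsr
from .simulate import SimConfig, simulate_crac_reads, simulate_genome


def motif_recovery_rate(n_runs: int = 100, base_seed: int = 1) -> float:
    """Fraction of seeded default simulations whose top-ranked hexamer
    matches the planted T(T/C/G)AAAC motif."""
    wins = 0
    for i in range(n_runs):
        cfg = SimConfig(seed=(base_seed * 1000 + i) % (2**31 - 1))
        genome, annotation, truth = simulate_genome(cfg)
        crac = simulate_crac_reads(genome, annotation, truth, cfg)
        clusters = call_clusters(crac, genome)
        kmers = kmer_enrichment(clusters, seed=cfg.seed)
        wins += top_kmer_is_dsr(kmers)
    return wins / n_runs


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mu))


def null_type1_rate(
    seed: int, n_genes: int = 2000, n_reps: int = 3, dispersion: float = 0.05, alpha: float = 0.05
) -> float:
    """Fraction p < alpha on a 3v3 null NB simulation with no planted changes."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(20), np.log(1000), n_genes))
    cols = {f"wt{i}": _nb_counts(rng, mu, dispersion) for i in range(n_reps)}
    cols |= {f"mut{i}": _nb_counts(rng, mu, dispersion) for i in range(n_reps)}
    cm = CountMatrix(
        pd.DataFrame(cols),
        {c: ("WT" if c.startswith("wt") else "mutant") for c in cols},
    )
    return float((nb_wald_test(cm)["p"] < alpha).mean())


def planted_fc_sensitivity(
    seed: int,
    n_genes: int = 2000,
    n_planted: int = 200,
    mu0: float = 100.0,
    fold: float = 4.0,
    dispersion: float = 0.05,
) -> float:
    """Fraction of planted ``fold``-up genes at mean mu0 called up (3v3)."""
    rng = np.random.default_rng(seed)
    mu = np.full(n_genes, mu0)
    fc = np.ones(n_genes)
    fc[:n_planted] = fold
    cols = {f"wt{i}": _nb_counts(rng, mu, dispersion) for i in range(3)}
    cols |= {f"mut{i}": _nb_counts(rng, mu * fc, dispersion) for i in range(3)}
    cm = CountMatrix(
        pd.DataFrame(cols),
        {c: ("WT" if c.startswith("wt") else "mutant") for c in cols},
    )
    res = classify_de(nb_wald_test(cm))
    return float((res["call"].iloc[:n_planted] == "up").mean())
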