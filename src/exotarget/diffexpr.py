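"""Negative-binomial differential expression and gene-set statistics.

A defined NB Wald test between WT and mutant replicates: median-of-ratios
size factors, method-of-moments dispersions moderated toward a mean-rank
trend, a Wald statistic on the log2 fold change with delta-method
standard errors, BH adjustment, the >1.5-fold & p<0.05 call rule,
per-class tallies with round-half-up percentages, and hypergeometric
gene-set enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass
class CountMatrix:
    """Integer counts (features x samples) with a condition map."""

    counts: pd.DataFrame
    conditions: dict[str, str]  # sample -> {WT, mutant}
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition: {sorted(missing)}")
        bad = set(self.conditions.values()) - {"WT", "mutant"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        for cond in ("WT", "mutant"):
            if len(self.samples(cond)) < 2:
                raise ValueError(f"need >= 2 replicates for condition {cond}")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be > 0")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        conditions = dict(zip(sheet["sample"], sheet["condition"]))
        return cls(counts[list(conditions)], conditions)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Falls back to total-count ratios (with a warning) when no feature is
    nonzero in all samples.
    """
    arr = counts.to_numpy(float)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any():
        loggeo = np.log(arr[all_pos]).mean(axis=1)
        factors = np.exp(np.median(np.log(arr[all_pos]) - loggeo[:, None], axis=0))
    else:
        log.warning("no feature with nonzero counts in all samples; using total-count ratios")
        totals = arr.sum(axis=0)
        factors = totals / stats.gmean(totals)
    factors = factors / stats.gmean(factors)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _mom_dispersions(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene method-of-moments dispersion, averaged over conditions.

    Can be negative (variance below Poisson); clipping and moderation are
    the caller's job so the cross-gene trend stays unbiased.
    """
    num = np.zeros(norm.shape[0])
    den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += w * a
        den += w
    return num / den


def _trend_dispersion(mean_expr: np.ndarray, alpha_raw: np.ndarray, window: int = 101) -> np.ndarray:
    """Running mean of raw dispersions over genes ranked by expression."""
    order = np.argsort(mean_expr, kind="mergesort")
    s = pd.Series(alpha_raw[order])
    trend_sorted = s.rolling(window, min_periods=1, center=True).mean().to_numpy()
    trend = np.empty_like(trend_sorted)
    trend[order] = trend_sorted
    return trend


def nb_wald_test(
    cm: CountMatrix,
    dispersion_mode: str = "trended",
    pseudocount: float = 0.5,
    shrink_weight: float = 0.2,
) -> pd.DataFrame:
    """NB Wald test of mutant vs WT.

    Dispersions: per-gene method of moments on normalized counts, shrunk
    toward a running-mean trend over genes of similar expression
    (``trended``) or replaced by the pooled constant (``pooled``).
    log2FC comes from normalized condition means with a pseudocount; the
    Wald SE uses the NB delta method var(log mean) ~ (1/mu + alpha)/r.
    Genes where one condition is all zero are flagged and get p = 1 with
    the log2FC clamped to +-10.

    Returns a DataFrame with log2fc, se, dispersion, p, q, mean_wt,
    mean_mut and flagged columns; ``call`` is added by classify_de.
    """
    if dispersion_mode not in ("trended", "pooled"):
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    if cm.size_factors is None:
        cm.size_factors = estimate_size_factors(cm.counts)
    norm = cm.counts.to_numpy(float) / cm.size_factors.to_numpy(float)[None, :]
    cols = list(cm.counts.columns)
    idx_wt = np.array([cols.index(s) for s in cm.samples("WT")])
    idx_mut = np.array([cols.index(s) for s in cm.samples("mutant")])

    alpha_raw = _mom_dispersions(norm, [idx_wt, idx_mut])
    mean_expr = norm.mean(axis=1)
    if dispersion_mode == "pooled":
        alpha = np.full_like(alpha_raw, max(float(alpha_raw.mean()), 1e-8))
    else:
        trend = np.clip(_trend_dispersion(mean_expr, alpha_raw), 1e-8, 10.0)
        alpha = np.clip(trend + shrink_weight * (alpha_raw - trend), 1e-8, 10.0)

    mw = norm[:, idx_wt].mean(axis=1)
    mm = norm[:, idx_mut].mean(axis=1)
    rw, rm = len(idx_wt), len(idx_mut)

    log2fc = np.log2((mm + pseudocount) / (mw + pseudocount))
    se = np.sqrt(
        (1.0 / (mw + pseudocount) + alpha) / rw
        + (1.0 / (mm + pseudocount) + alpha) / rm
    ) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))

    zero_wt = (cm.counts.to_numpy()[:, idx_wt] == 0).all(axis=1)
    zero_mut = (cm.counts.to_numpy()[:, idx_mut] == 0).all(axis=1)
    flagged = zero_wt | zero_mut
    p = np.where(flagged, 1.0, p)
    log2fc = np.clip(log2fc, -10.0, 10.0)

    res = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "dispersion": alpha,
            "p": p,
            "q": bh_adjust(p),
            "mean_wt": mw,
            "mean_mut": mm,
            "flagged": flagged,
        },
        index=cm.counts.index,
    )
    res.index.name = "feature_id"
    return res


def classify_de(results: pd.DataFrame, fold: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Add the call column: up/down iff fold change > ``fold`` (strict) and p < alpha."""
    fc = np.power(2.0, results["log2fc"].to_numpy())
    sig = results["p"].to_numpy() < alpha
    call = np.where(
        (fc > fold) & sig, "up", np.where((1.0 / fc > fold) & sig, "down", "unchanged")
    )
    out = results.copy()
    out["call"] = call
    return out


def round_half_up_pct(count: int, total: int) -> int:
    """Integer percentage with half-up rounding (159/445 -> 36)."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * count / total + 0.5))


def tally_classes(
    calls: Mapping[str, str], fclasses: Mapping[str, str]
) -> pd.DataFrame:
    """Counts and rounded percentages by feature class per call direction.

    ``calls`` maps feature id -> {up, down, unchanged}; ``fclasses`` maps
    feature id -> feature class.  Rows: (direction, fclass, count, pct),
    where pct is the round-half-up integer percentage within that
    direction.
    """
    rows = []
    for direction in ("up", "down"):
        ids = [fid for fid, c in calls.items() if c == direction]
        total = len(ids)
        by_class: dict[str, int] = {}
        for fid in ids:
            by_class[fclasses[fid]] = by_class.get(fclasses[fid], 0) + 1
        for fclass in sorted(by_class, key=lambda k: (-by_class[k], k)):
            rows.append(
                dict(
                    direction=direction,
                    fclass=fclass,
                    count=by_class[fclass],
                    pct=round_half_up_pct(by_class[fclass], total),
                    total=total,
                )
            )
    return pd.DataFrame(rows, columns=["direction", "fclass", "count", "pct", "total"])


@dataclass
class GeneSetResult:
    set_id: str
    k: int  # overlap
    n: int  # query size
    K: int  # set size
    N: int  # universe size
    p: float  # hypergeometric upper tail P(X >= k)


def hypergeom_enrichment(
    query_ids: Iterable[str],
    set_ids: Iterable[str],
    universe_ids: Iterable[str],
    set_id: str = "geneset",
) -> GeneSetResult:
    """Upper-tail hypergeometric enrichment of a gene set in a query list."""
    universe = set(universe_ids)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_ids)
    gene_set = set(set_ids)
    if not query <= universe or not gene_set <= universe:
        raise ValueError("query and set must be subsets of the universe")
    N, K, n = len(universe), len(gene_set), len(query)
    k = len(query & gene_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return GeneSetResult(set_id, k, n, K, N, min(p, 1.0))
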