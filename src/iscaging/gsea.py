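"""Preranked gene-set enrichment analysis.

Genes are ranked by a differential-expression metric (log fold-change by
default); the enrichment score of a set is the signed extremum of a running
sum that rises by the normalized |metric|^weight on set hits and falls by
1/(N - n_set) on misses.  The null is built from gene-label permutations
preserving set size; NES divides the ES by the mean |null ES| of matching
sign, and the nominal p counts permutations with |null ES| >= |ES| (with a
+1 pseudo-count), followed by Benjamini-Hochberg across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import adjust_pvalues

log = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by ranking metric, descending, no duplicates."""

    genes: list
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        self.metric = np.asarray(self.metric, dtype=float)
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("ranking metric must be finite")


def rank_genes(de_results: pd.DataFrame, metric: str = "logfc") -> RankedList:
    """Rank genes by DE log fold-change (descending); ties break by gene id.

    ``metric="signed_logp"`` ranks by sign(logFC) * -log10(p) instead.
    """
    if de_results.index.duplicated().any():
        dups = de_results.index[de_results.index.duplicated()][:5]
        raise ValueError(f"duplicate gene ids: {list(dups)}")
    if metric == "logfc":
        values = de_results["logfc"].astype(float)
    elif metric == "signed_logp":
        p = de_results["p"].astype(float).clip(lower=1e-300)
        values = np.sign(de_results["logfc"]) * (-np.log10(p))
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    order = sorted(zip(-values.to_numpy(), de_results.index))
    n_ties = len(values) - values.nunique()
    if n_ties:
        log.info("%d tied metric values; ties broken by gene id", n_ties)
    genes = [g for _, g in order]
    return RankedList(genes=genes, metric=np.array([-v for v, _ in order]))


def enrichment_score(ranked: RankedList, gene_set, weight: float = 1.0):
    """ES and the full running-sum profile of one gene set.

    Hits raise the running sum by |metric|^weight (normalized over the set's
    hits); misses lower it by 1/(N - n_hits).  The ES is the running sum's
    signed extremum.  A set covering every ranked gene never decrements; its
    ES is 1 by convention and flagged degenerate.
    """
    hits = np.isin(ranked.genes, list(gene_set))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    n = len(ranked.genes)
    if n_hits == n:
        return 1.0, np.ones(n), True
    w = np.abs(ranked.metric) ** weight
    denom = w[hits].sum()
    if denom == 0:  # all-zero metric on hits: fall back to unweighted steps
        step_hit = np.where(hits, 1.0 / n_hits, 0.0)
    else:
        step_hit = np.where(hits, w / denom, 0.0)
    step_miss = np.where(hits, 0.0, -1.0 / (n - n_hits))
    running = np.cumsum(step_hit + step_miss)
    es = float(running[np.argmax(np.abs(running))])
    return es, running, False


def _es_only(metric_abs_w: np.ndarray, hit_idx: np.ndarray, n: int) -> float:
    """ES for hit positions ``hit_idx`` (sorted), used by the permutation null."""
    n_hits = hit_idx.size
    w = metric_abs_w[hit_idx]
    denom = w.sum()
    inc = w / denom if denom > 0 else np.full(n_hits, 1.0 / n_hits)
    miss = 1.0 / (n - n_hits)
    # running sum needs evaluation only at hit positions and just before them
    before = np.cumsum(inc) - inc - (hit_idx - np.arange(n_hits)) * miss
    after = before + inc
    # the sum ends at exactly 0, so 0 bounds both extrema candidates
    lo = min(float(before.min()), 0.0)
    hi = max(float(after.max()), 0.0)
    return hi if hi >= -lo else lo


def leading_edge(ranked: RankedList, gene_set, weight: float = 1.0) -> list:
    es, running, degenerate = enrichment_score(ranked, gene_set, weight)
    if degenerate:
        return [g for g in ranked.genes if g in set(gene_set)]
    peak = int(np.argmax(np.abs(running)))
    gs = set(gene_set)
    if es >= 0:
        return [g for g in ranked.genes[:peak + 1] if g in gs]
    return [g for g in ranked.genes[peak:] if g in gs]


def gsea_permutation(ranked: RankedList, gene_sets: dict, n_perm: int = 10000,
                     weight: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Permutation GSEA over several sets; returns the result table.

    The null preserves each set's hit count by drawing random gene labels;
    nominal p = (1 + #{|null ES| >= |ES|}) / (n_perm + 1); BH across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked.genes)
    w = np.abs(ranked.metric) ** weight
    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, genes in gene_sets.items():
        hits = np.isin(ranked.genes, list(genes))
        n_hits = int(hits.sum())
        if n_hits == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the ranked list")
        if n_hits > n:
            raise ValueError(f"gene set {name!r} larger than the ranked list")
        es, _, degenerate = enrichment_score(ranked, genes, weight)
        if degenerate:
            rows.append({"set": name, "es": es, "nes": np.nan, "p": 1.0,
                         "n_genes": n_hits, "degenerate": True,
                         "leading_edge": ""})
            continue
        if n_hits not in null_cache:
            null = np.empty(n_perm)
            for i in range(n_perm):
                idx = np.sort(rng.choice(n, size=n_hits, replace=False))
                null[i] = _es_only(w, idx, n)
            null_cache[n_hits] = null
        null = null_cache[n_hits]
        same_sign = null[np.sign(null) == np.sign(es)]
        nes = es / np.abs(same_sign).mean() if same_sign.size else np.nan
        p = float((1 + np.sum(np.abs(null) >= abs(es) - 1e-12)) / (n_perm + 1))
        rows.append({"set": name, "es": es, "nes": nes, "p": p,
                     "n_genes": n_hits, "degenerate": False,
                     "leading_edge": ",".join(leading_edge(ranked, genes, weight))})
    out = pd.DataFrame(rows).set_index("set")
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method="bh")
    out["n_perm"] = n_perm
    return out
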