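"""QC filtering, normalization, embedding, clustering and cell-type annotation.

The steps mirror the standard droplet scRNA-seq workflow: drop cells with
too few / too many detected genes or a high mitochondrial fraction,
log-normalize to a fixed per-cell total, embed the top variable genes by
PCA, cluster a shared-nearest-neighbor graph with the Louvain algorithm,
and map clusters to cell types by marker-set mean expression.  Samples are
co-embedded by a joint PCA; no cross-sample integration is performed (the
bundled synthetic cohorts are batch-free).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import MITO_PREFIX, CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)

NORM_TARGET = 1e4


@dataclass
class QCThresholds:
    """Exclusive bounds: a cell is kept iff
    min_genes <= detected genes <= max_genes and mito fraction <= max_mito."""

    min_genes: int = 200
    max_genes: int = 5000
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValueError("need 0 < min_genes < max_genes")
        if not (0 <= self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class Embedding:
    """PCA coordinates (cells x components) with variance shares and the
    gene subset / scaling used to produce them."""

    coords: np.ndarray
    variance_share: np.ndarray
    cell_ids: pd.Index
    genes_used: list
    scaled: bool


def qc_metrics(counts: CountMatrix) -> pd.DataFrame:
    mat = counts.counts
    n_genes = np.asarray((mat > 0).sum(axis=0)).ravel()
    totals = np.asarray(mat.sum(axis=0)).ravel()
    mito = np.asarray(counts.gene_ids.str.startswith(MITO_PREFIX))
    mito_counts = np.asarray(mat[mito].sum(axis=0)).ravel() if mito.any() \
        else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    return pd.DataFrame({"n_genes": n_genes, "total_counts": totals,
                         "mito_fraction": frac}, index=counts.cell_ids)


def qc_filter(counts: CountMatrix, thresholds: QCThresholds | None = None):
    """Remove cells violating the QC thresholds; the gene axis is unchanged.

    Returns ``(filtered, removal_log)`` where the log names each removed
    cell and the reason(s).  Raises if nothing survives.
    """
    thr = thresholds or QCThresholds()
    qc = qc_metrics(counts)
    low = qc["n_genes"] < thr.min_genes
    high = qc["n_genes"] > thr.max_genes
    mito = qc["mito_fraction"] > thr.max_mito_fraction
    bad = low | high | mito
    reasons = []
    for cid in qc.index[bad]:
        why = []
        if low[cid]:
            why.append(f"genes<{thr.min_genes}")
        if high[cid]:
            why.append(f"genes>{thr.max_genes}")
        if mito[cid]:
            why.append(f"mito>{thr.max_mito_fraction:g}")
        reasons.append((cid, ";".join(why)))
    removal_log = pd.DataFrame(reasons, columns=["cell", "reason"]).set_index("cell")
    if bad.all():
        raise ValueError(
            "QC removed every cell; review thresholds "
            f"(min_genes={thr.min_genes}, max_genes={thr.max_genes}, "
            f"max_mito={thr.max_mito_fraction})")
    kept = counts.subset_cells((~bad).to_numpy())
    qckept = qc.loc[~bad]
    kept.cells = kept.cells.drop(columns=qc.columns, errors="ignore").join(qckept)
    log.info("QC removed %d/%d cells", int(bad.sum()), len(qc))
    return kept, removal_log


def normalize(counts: CountMatrix) -> NormalizedMatrix:
    """log(1 + 1e4 * count / cell_total), natural log, dense genes x cells."""
    totals = np.asarray(counts.counts.sum(axis=0)).ravel()
    if (totals <= 0).any():
        raise ValueError("cell(s) with zero total counts; run qc_filter first")
    dense = counts.counts.toarray().astype(np.float64)
    values = np.log1p(NORM_TARGET * dense / totals[None, :])
    return NormalizedMatrix(values, counts.genes, counts.cells)


def select_variable_genes(norm: NormalizedMatrix, n_top: int = 2000) -> list:
    """Top genes by standardized dispersion (dispersion z-scored within
    mean-expression bins), the classic variable-gene heuristic."""
    mean = norm.values.mean(axis=1)
    var = norm.values.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    n_bins = 20
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.minimum(np.arange(len(mean)) * n_bins // max(len(mean), 1),
                             n_bins - 1)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        m = bins == b
        if m.sum() > 1:
            mu, sd = disp[m].mean(), disp[m].std()
            z[m] = (disp[m] - mu) / (sd if sd > 0 else 1.0)
    n_top = min(n_top, len(mean))
    top = np.argsort(-z, kind="stable")[:n_top]
    return list(norm.gene_ids[np.sort(top)])


def embed(norm: NormalizedMatrix, n_components: int = 30,
          n_top_genes: int = 2000, scale: bool = True) -> Embedding:
    """PCA of the centered (optionally unit-variance) variable-gene matrix.

    Component signs are fixed so the largest-magnitude gene loading of each
    component is positive, making the embedding deterministic.
    """
    genes_used = select_variable_genes(norm, n_top_genes)
    sub = norm.values[norm.gene_ids.get_indexer(genes_used)].T  # cells x genes
    n_cells, n_genes = sub.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds matrix rank bound "
            f"{min(n_cells, n_genes)}")
    x = sub - sub.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        x = x / np.where(sd > 0, sd, 1.0)
    solver = "full" if min(n_cells, n_genes) < 500 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=0)
    coords = pca.fit_transform(x)
    # sign convention: largest-|loading| entry of each component positive
    comp = pca.components_
    flip = np.sign(comp[np.arange(comp.shape[0]),
                        np.argmax(np.abs(comp), axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]
    return Embedding(coords=coords, variance_share=pca.explained_variance_ratio_,
                     cell_ids=norm.cell_ids, genes_used=genes_used, scaled=scale)


def snn_graph(coords: np.ndarray, n_neighbors: int = 15) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = coords.shape[0]
    if n_neighbors <= 0:
        raise ValueError("n_neighbors must be positive")
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_sets = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[j])
            jac = shared / (2 * n_neighbors - shared)
            if jac > 1 / 15:  # prune weak links, as the SNN convention does
                edges.append((i, j))
                weights.append(jac)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster(embedding: Embedding, n_neighbors: int = 15,
            resolution: float = 2.5, seed: int = 0,
            n_components: int | None = None) -> pd.Series:
    """Louvain community detection on the SNN graph; labels 0..K-1 ordered
    by decreasing cluster size.  Deterministic given the seed."""
    coords = embedding.coords if n_components is None \
        else embedding.coords[:, :n_components]
    if coords.shape[0] == 1:
        return pd.Series([0], index=embedding.cell_ids, name="cluster")
    k = min(n_neighbors, coords.shape[0] - 1)
    g = snn_graph(coords, k)
    random.seed(seed)  # python-igraph draws from Python's random module
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    order = np.argsort([-np.sum(labels == c) for c in range(labels.max() + 1)],
                       kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(c)] for c in labels])
    return pd.Series(labels, index=embedding.cell_ids, name="cluster")


def annotate_types(norm: NormalizedMatrix, labels: pd.Series,
                   marker_sets: dict[str, list[str]]):
    """Assign each cluster the type whose marker mean expression is maximal.

    Ties break lexicographically (and are logged).  Returns
    ``(per_cell_types, per_condition_proportions)``; proportions are over
    types within each condition and sum to 1.
    """
    if not marker_sets:
        raise ValueError("marker_sets is empty")
    present = {}
    for t, genes in sorted(marker_sets.items()):
        found = [g for g in genes if g in norm.gene_ids]
        if not found:
            raise ValueError(f"no marker gene of type {t!r} found in the matrix")
        present[t] = norm.gene_ids.get_indexer(found)
    assign = {}
    for c in sorted(labels.unique()):
        cells = (labels == c).to_numpy()
        means = {t: norm.values[np.ix_(rows, cells)].mean()
                 for t, rows in present.items()}
        best = max(means.values())
        winners = sorted(t for t, v in means.items() if v == best)
        if len(winners) > 1:
            log.info("cluster %s: marker tie between %s; assigning %r",
                     c, winners, winners[0])
        assign[c] = winners[0]
    types = labels.map(assign).rename("cell_type")
    props = None
    if "condition" in norm.cells.columns:
        tab = pd.crosstab(norm.cells["condition"], types)
        props = tab.div(tab.sum(axis=1), axis=0)
    return types, props
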