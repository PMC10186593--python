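"""Pathway module scoring and signature expression-ratio compartment analysis.

``module_score`` implements control-bin gene-set scoring: the score of a
cell is the mean expression of the set genes minus the mean of random
control genes drawn from the same dataset-average-expression bins, so the
score is centered with respect to expression level.  The ratio analysis
summarizes per-gene condition-vs-young mean-expression ratios into six
fixed compartments: (0,0.5], (0.5,0.8], (0.8,1], (1,1.2], (1.2,1.5], (1.5,inf).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .io import NormalizedMatrix, TestResult
from .stats import manova_two_response
from .synthetic_data import COMPARTMENT_EDGES, compartment_of

log = logging.getLogger(__name__)


def module_score(norm: NormalizedMatrix, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> pd.Series:
    """Per-cell module score of one gene set against binned random controls.

    Genes are binned into ``n_bins`` equal-frequency bins of dataset-average
    expression; each set gene contributes ``n_ctrl`` control genes sampled
    with replacement from its bin (set genes excluded from the control
    pool), and the score is
    mean(set expression) - mean(pooled control expression).
    """
    if n_bins > norm.values.shape[0]:
        raise ValueError(f"n_bins={n_bins} exceeds gene count {norm.values.shape[0]}")
    in_set = norm.gene_ids.get_indexer([g for g in gene_set
                                        if g in norm.gene_ids])
    if in_set.size == 0:
        raise ValueError("gene set has empty intersection with the matrix")
    avg = norm.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.arange(len(avg)) * n_bins // len(avg)
    rng = np.random.default_rng(seed)
    in_set_mask = np.zeros(len(avg), dtype=bool)
    in_set_mask[in_set] = True
    ctrl_idx = []
    for gi in in_set:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set_mask)
        if pool.size == 0:  # a bin fully covered by the set: fall back
            pool = np.flatnonzero(bins == bins[gi])
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)
    score = norm.values[in_set].mean(axis=0) - norm.values[ctrl_idx].mean(axis=0)
    return pd.Series(score, index=norm.cell_ids, name="module_score")


def score_gene_sets(norm: NormalizedMatrix, gene_sets: dict, n_bins: int = 24,
                    n_ctrl: int = 100, seed: int = 0) -> pd.DataFrame:
    """Module scores for several sets (one column per set, shared binning seed)."""
    cols = {name: module_score(norm, genes, n_bins, n_ctrl, seed)
            for name, genes in gene_sets.items()}
    return pd.DataFrame(cols)


def mean_score_by_mouse(scores: pd.Series | pd.DataFrame,
                        meta: pd.DataFrame, scope: pd.Index | None = None):
    """Per-mouse mean scores and per-condition means (mean over the mice).

    The mouse is the experimental unit: a condition's mean is the unweighted
    mean of its mice's means.
    """
    df = pd.DataFrame(scores).copy()
    if scope is not None:
        df = df.loc[df.index.intersection(scope)]
    if df.empty:
        raise ValueError("no cells in scope")
    joined = df.join(meta[["mouse", "condition"]])
    if joined["mouse"].isna().any():
        raise ValueError("cells in scope missing mouse metadata")
    by_mouse = joined.groupby(["condition", "mouse"], observed=True).mean()
    by_condition = by_mouse.groupby(level="condition", observed=True).mean()
    return by_mouse, by_condition


def mean_expression_by_condition(norm: NormalizedMatrix, meta: pd.DataFrame,
                                 cluster: str, genes,
                                 cluster_col: str = "cell_type",
                                 scale: str = "linear") -> pd.DataFrame:
    """Per-gene mean expression in one cluster, per mouse then per condition.

    ``scale="linear"`` (default) averages the depth-normalized values
    (expm1 of the log-normalized matrix), the convention under which ratios
    of means estimate expression-rate ratios; ``scale="log"`` averages the
    log-normalized values directly.  Mice with no cell in the cluster are
    skipped with a warning.
    """
    if cluster_col not in meta.columns:
        raise ValueError(f"metadata has no {cluster_col!r} column")
    mask = (meta[cluster_col] == cluster).to_numpy()
    if not mask.any():
        raise ValueError(f"cluster {cluster!r} has no cells")
    gene_rows = norm.gene_ids.get_indexer(list(genes))
    if (gene_rows < 0).any():
        missing = [g for g, r in zip(genes, gene_rows) if r < 0]
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    vals = norm.values[np.ix_(gene_rows, mask)]
    if scale == "linear":
        vals = np.expm1(vals)
    elif scale != "log":
        raise ValueError("scale must be 'linear' or 'log'")
    sub = meta.loc[mask]
    per_mouse = {}
    for (cond, mouse), grp in sub.groupby(["condition", "mouse"], observed=True):
        cols = sub.index.get_indexer(grp.index)
        per_mouse[(cond, mouse)] = vals[:, cols].mean(axis=1)
    all_mice = meta.groupby(["condition", "mouse"], observed=True).size().index
    for key in all_mice:
        if key not in per_mouse:
            log.warning("mouse %s has no cells in cluster %r; skipped", key[1], cluster)
    frame = pd.DataFrame(per_mouse, index=list(genes))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["condition", "mouse"])
    return frame.T.groupby(level="condition", observed=True).mean().T


@dataclass
class RatioTable:
    """Per-gene contrast/reference expression ratios with compartment bins."""

    table: pd.DataFrame          # columns: ratio, compartment
    contrast: str
    reference: str
    excluded: list               # genes dropped for zero reference mean


def expression_ratio(means: pd.DataFrame, contrast: str,
                     reference: str = "Y") -> RatioTable:
    """Contrast / reference ratio per gene; genes with zero reference mean
    are excluded (the signature is restricted to genes expressed in young
    mice) and reported."""
    for c in (contrast, reference):
        if c not in means.columns:
            raise ValueError(f"condition {c!r} not present in means table")
    ref = means[reference]
    ok = ref > 0
    excluded = list(means.index[~ok])
    if excluded:
        log.info("excluding %d genes with zero %s mean", len(excluded), reference)
    if not ok.any():
        raise ValueError("no gene with positive reference mean")
    ratio = (means.loc[ok, contrast] / ref[ok]).rename("ratio")
    ratio = ratio[ratio > 0]
    table = pd.DataFrame({"ratio": ratio,
                          "compartment": compartment_of(ratio.to_numpy())})
    return RatioTable(table=table, contrast=contrast, reference=reference,
                      excluded=excluded)


def compartment_summary(ratios: RatioTable):
    """Six-bin percentage vector (sums to 100) plus the fraction of genes
    at or below ratio 1 (compartments 1-3), as printed percentages."""
    if ratios.table.empty:
        raise ValueError("empty ratio table")
    counts = np.bincount(ratios.table["compartment"], minlength=7)[1:7]
    pct = 100.0 * counts / counts.sum()
    below_one = float(pct[:3].sum())
    vec = pd.Series(pct, index=[f"compartment_{i}" for i in range(1, 7)],
                    name=f"{ratios.contrast}/{ratios.reference}")
    assert abs(vec.sum() - 100.0) < 1e-9
    return vec, below_one


def compare_ratio_distributions(a: RatioTable, b: RatioTable) -> TestResult:
    """KS comparison of two ratio distributions (cumulative-density view)."""
    from .stats import ks_two_sample
    return ks_two_sample(a.table["ratio"].to_numpy(), b.table["ratio"].to_numpy())


def gaussian_ellipse_95(points: np.ndarray) -> dict:
    """Mean + covariance 95% ellipse (2 df chi-squared radius) of n x 2 points."""
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    degenerate = len(pts) < 3 or np.allclose(pts, pts[0])
    if degenerate:
        return {"mean": mean.tolist(), "semi_axes": [0.0, 0.0],
                "angle": 0.0, "degenerate": True}
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    radius2 = st.chi2.ppf(0.95, df=2)
    semi = np.sqrt(np.clip(evals, 0, None) * radius2)[::-1]
    angle = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
    return {"mean": mean.tolist(), "semi_axes": semi.tolist(),
            "angle": angle, "degenerate": bool(np.isclose(semi[0], 0))}


def bivariate_coordination(mouse_means: pd.DataFrame, pathway_a: str,
                           pathway_b: str):
    """MANOVA of two pathways' per-mouse mean scores across conditions,
    plus per-condition 95% Gaussian ellipse parameters.

    ``mouse_means`` is the per-(condition, mouse) table from
    :func:`mean_score_by_mouse`.
    """
    for pw in (pathway_a, pathway_b):
        if pw not in mouse_means.columns:
            raise ValueError(f"pathway {pw!r} not in mouse mean table")
    conds = mouse_means.index.get_level_values("condition")
    counts = pd.Series(conds).value_counts()
    if (counts < 2).any():
        raise ValueError("each condition needs >= 2 mice")
    Y = mouse_means[[pathway_a, pathway_b]].to_numpy()
    result = manova_two_response(Y, conds.to_numpy())
    ellipses = {
        cond: gaussian_ellipse_95(Y[conds == cond])
        for cond in sorted(set(conds))
    }
    return result, ellipses
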