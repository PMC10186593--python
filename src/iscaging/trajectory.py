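"""Principal-graph trajectory, pseudotime and maturation-delay statistics.

The trajectory is a minimum spanning tree over cluster medoids in the PCA
embedding.  Each cell is projected onto the nearest point of an edge
incident to its cluster's medoid; pseudotime is the geodesic distance from
the root (Stem) medoid to the projection, min-max normalized to [0, 1].
Cells are dichotomized into *main* (clusters on the unique root->terminus
tree path), *side* (clusters hanging off that path) and *excluded*
(clusters beyond the terminus).  On top of this sit the branch-point
statistics: cell-type transition tests across pseudotime compartments,
per-type emergence quantiles, segment-wise module-score profiles, and a
transcript co-expression index for an early/late marker pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph

from .io import NormalizedMatrix, TestResult
from .stats import chisq_mc

log = logging.getLogger(__name__)


@dataclass
class TrajectoryGraph:
    vertices: pd.DataFrame       # cluster label -> medoid coordinates
    edges: list                  # (label_a, label_b, length)
    root: str
    projections: pd.DataFrame    # per cell: edge_a, edge_b, t, pseudotime
    pseudotime: pd.Series        # normalized geodesic distance from root
    labels: pd.Series            # per-cell cluster/type label
    _adj: dict = field(default_factory=dict, repr=False)

    def neighbors(self, v: str) -> list:
        return self._adj.get(v, [])

    def tree_path(self, target: str) -> list:
        """Unique path of vertex labels from the root to ``target``."""
        parent = {self.root: None}
        stack = [self.root]
        while stack:
            v = stack.pop()
            for w, _ in self.neighbors(v):
                if w not in parent:
                    parent[w] = v
                    stack.append(w)
        if target not in parent:
            raise ValueError(f"vertex {target!r} not reachable from root")
        path = [target]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])
        return path[::-1]


def learn_trajectory(coords: np.ndarray, labels: pd.Series,
                     root_type: str) -> TrajectoryGraph:
    """Build the medoid-MST trajectory and per-cell pseudotime.

    ``coords`` are embedding coordinates aligned with ``labels`` (per-cell
    cluster or annotated-type labels); ``root_type`` names the root cluster.
    """
    labels = pd.Series(labels)
    uniq = sorted(labels.unique().tolist())
    if root_type not in uniq:
        raise ValueError(f"root type {root_type!r} not among labels {uniq}")
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters to build a trajectory")
    # medoid: the member closest to its cluster mean
    medoids = {}
    for u in uniq:
        pts = coords[(labels == u).to_numpy()]
        center = pts.mean(axis=0)
        medoids[u] = pts[np.argmin(((pts - center) ** 2).sum(axis=1))]
    vm = np.vstack([medoids[u] for u in uniq])
    dist = np.sqrt(((vm[:, None, :] - vm[None, :, :]) ** 2).sum(-1))
    mst = csgraph.minimum_spanning_tree(dist).toarray()
    edges = []
    adj: dict[str, list] = {u: [] for u in uniq}
    for i in range(len(uniq)):
        for j in range(len(uniq)):
            if mst[i, j] > 0:
                a, b, w = uniq[i], uniq[j], float(mst[i, j])
                edges.append((a, b, w))
                adj[a].append((b, w))
                adj[b].append((a, w))
    assert len(edges) == len(uniq) - 1

    # geodesic vertex distances from the root
    sym = mst + mst.T
    dvert = csgraph.dijkstra(sym, indices=uniq.index(root_type))
    vdist = dict(zip(uniq, dvert))

    # project each cell onto the nearest point of an edge incident to its medoid
    rows = []
    for u in uniq:
        mask = (labels == u).to_numpy()
        pts = coords[mask]
        ids = labels.index[mask]
        incident = adj[u]
        if not incident:  # single-vertex degenerate graphs are rejected above
            continue
        best_d = np.full(len(pts), np.inf)
        best = [None] * len(pts)
        for w, elen in incident:
            a, b = medoids[u], medoids[w]
            ab = b - a
            denom = float(ab @ ab)
            t = np.clip(((pts - a) @ ab) / denom if denom > 0 else 0.0, 0, 1)
            proj = a + t[:, None] * ab
            d = np.sqrt(((pts - proj) ** 2).sum(axis=1))
            better = d < best_d
            for i in np.flatnonzero(better):
                best[i] = (w, float(t[i]), elen)
            best_d = np.minimum(best_d, d)
        for cid, choice in zip(ids, best):
            w, t, elen = choice
            # pseudotime along the edge from u towards w
            pt = min(vdist[u] + t * elen, vdist[w] + (1 - t) * elen)
            rows.append((cid, u, w, t, pt))
    proj = pd.DataFrame(rows, columns=["cell", "edge_a", "edge_b", "t",
                                       "raw_pseudotime"]).set_index("cell")
    proj = proj.loc[labels.index]
    raw = proj["raw_pseudotime"]
    span = raw.max() - raw.min()
    pt_norm = (raw - raw.min()) / (span if span > 0 else 1.0)
    proj["pseudotime"] = pt_norm
    vertices = pd.DataFrame(vm, index=pd.Index(uniq, name="cluster"))
    return TrajectoryGraph(vertices=vertices, edges=edges, root=root_type,
                           projections=proj,
                           pseudotime=pt_norm.rename("pseudotime"),
                           labels=labels, _adj=adj)


def select_and_dichotomize(traj: TrajectoryGraph, terminus_type: str) -> pd.Series:
    """Per-cell {main, side, excluded} relative to the root->terminus path.

    Main cells belong to clusters on the path; side cells belong to
    branches attached to the path at or before the terminus; cells whose
    cluster lies beyond the terminus are excluded.
    """
    if terminus_type not in traj.vertices.index:
        raise ValueError(f"terminus {terminus_type!r} not in trajectory")
    path = traj.tree_path(terminus_type)
    on_path = set(path)
    flag = {}
    for v in traj.vertices.index:
        if v in on_path:
            flag[v] = "main"
        else:
            vpath = traj.tree_path(v)
            # where this cluster's route to the root meets the main path
            attach = next(x for x in vpath[::-1] if x in on_path)
            beyond = terminus_type in vpath[:-1] and attach == terminus_type
            flag[v] = "excluded" if beyond else "side"
    return traj.labels.map(flag).rename("dichotomy")


@dataclass
class CompartmentPartition:
    """Three contiguous pseudotime segments (early, mid, late)."""

    boundaries: tuple  # (b1, b2) with 0 < b1 < b2 < max pseudotime

    def assign(self, pseudotime) -> np.ndarray:
        pt = np.asarray(pseudotime, dtype=float)
        return np.searchsorted(np.asarray(self.boundaries), pt, side="right")

    @classmethod
    def tertiles(cls, pseudotime) -> "CompartmentPartition":
        pt = np.asarray(pseudotime, dtype=float)
        b1, b2 = np.quantile(pt, [1 / 3, 2 / 3])
        return cls(boundaries=(float(b1), float(b2)))


def compartment_transition_test(types, pseudotime, partition: CompartmentPartition,
                                conditions, n_sim: int = 2000, seed: int = 0):
    """Chi-squared (Monte-Carlo p) of cell type x condition per pseudotime
    compartment, plus a joint test pooling all compartments."""
    types = np.asarray(types)
    conditions = np.asarray(conditions)
    comp = partition.assign(pseudotime)
    results = {}
    pooled = None
    for k, name in enumerate(("early", "mid", "late")):
        mask = comp == k
        if not mask.any():
            raise ValueError(f"compartment {name!r} has no cells")
        tab = pd.crosstab(pd.Series(types[mask]), pd.Series(conditions[mask]))
        if (tab.to_numpy().sum(axis=0) == 0).any():
            raise ValueError(f"compartment {name!r} missing a condition")
        results[name] = chisq_mc(tab.to_numpy(), n_sim=n_sim, seed=seed + k)
        pooled = tab if pooled is None else pooled.add(tab, fill_value=0)
    joint = chisq_mc(pooled.to_numpy().astype(int), n_sim=n_sim, seed=seed + 3)
    return results, joint


def emergence_delay(types, pseudotime, main_flag, conditions, q: float = 0.05,
                    reference: str = "Y", min_cells: int = 20):
    """Per-type, per-condition emergence pseudotime (q-quantile of main-cell
    pseudotimes) and the delay relative to the reference condition.

    Types with fewer than ``min_cells`` main cells in a condition are
    reported missing (NaN) with a warning.
    """
    df = pd.DataFrame({"type": np.asarray(types),
                       "pt": np.asarray(pseudotime, dtype=float),
                       "main": np.asarray(main_flag),
                       "condition": np.asarray(conditions)})
    df = df[df["main"] == "main"]
    conds = sorted(df["condition"].unique().tolist())
    if reference not in conds:
        raise ValueError(f"reference condition {reference!r} absent")
    rows = []
    for t in sorted(df["type"].unique().tolist()):
        rec = {"type": t}
        for c in conds:
            sub = df[(df["type"] == t) & (df["condition"] == c)]
            if len(sub) < min_cells:
                log.warning("type %s has %d<%d main cells in %s; emergence "
                            "missing", t, len(sub), min_cells, c)
                rec[f"emergence_{c}"] = np.nan
            else:
                rec[f"emergence_{c}"] = float(np.quantile(sub["pt"], q))
        for c in conds:
            if c == reference:
                continue
            rec[f"delay_{c}"] = rec[f"emergence_{c}"] - rec[f"emergence_{reference}"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("type")


def branchpoint_module_profile(scores: pd.Series, traj: TrajectoryGraph,
                               terminus_type: str, conditions: pd.Series):
    """Mean module score per inter-branch-point segment per condition.

    Segments are the edges of the root->terminus main path, ordered by
    pseudotime; a segment with no cells yields a missing value.
    """
    path = traj.tree_path(terminus_type)
    segments = list(zip(path[:-1], path[1:]))
    proj = traj.projections
    scores = scores.loc[proj.index]
    conditions = pd.Series(conditions).loc[proj.index]
    out = {}
    for a, b in segments:
        on_seg = (((proj["edge_a"] == a) & (proj["edge_b"] == b))
                  | ((proj["edge_a"] == b) & (proj["edge_b"] == a))).to_numpy()
        seg_name = f"{a}->{b}"
        col = {}
        for c in sorted(conditions.unique().tolist()):
            mask = on_seg & (conditions == c).to_numpy()
            col[c] = float(scores[mask].mean()) if mask.any() else np.nan
        out[seg_name] = col
    return pd.DataFrame(out).T


def coexpression_index(norm: NormalizedMatrix, gene_early: str, gene_late: str,
                       scope_cells, positivity_quantile: float = 0.96):
    """Fraction of co-positive cells over the sum of single-positive counts.

    A cell is positive for a gene when its expression exceeds the per-gene
    ``positivity_quantile`` within the scope (the transcript analog of a
    top-4% staining threshold); the index is
    |co-positive| / (|positive_early| + |positive_late|).
    """
    scope = pd.Index(scope_cells)
    if scope.empty:
        raise ValueError("empty cell scope")
    cols = norm.cell_ids.get_indexer(scope)
    if (cols < 0).any():
        raise ValueError("scope contains unknown cell ids")
    out = {}
    positives = {}
    for g in (gene_early, gene_late):
        x = norm.row(g)[cols]
        if np.allclose(x, x[0]):
            raise ValueError(f"gene {g!r} has zero variance in scope; "
                             "positivity threshold undefined")
        thr = np.quantile(x, positivity_quantile)
        positives[g] = x > thr
    both = positives[gene_early] & positives[gene_late]
    n_e = int(positives[gene_early].sum())
    n_l = int(positives[gene_late].sum())
    denom = n_e + n_l
    index = float(both.sum() / denom) if denom else np.nan
    return {"index": index, "n_copositive": int(both.sum()),
            "n_positive_early": n_e, "n_positive_late": n_l,
            "n_cells": len(scope)}


def coexpression_by_condition(norm: NormalizedMatrix, meta: pd.DataFrame,
                              gene_early: str, gene_late: str, scope_mask,
                              positivity_quantile: float = 0.96) -> pd.DataFrame:
    """Co-expression index per condition over a shared cell scope."""
    scope_mask = np.asarray(scope_mask)
    rows = {}
    for c in sorted(meta["condition"].unique().tolist()):
        cells = meta.index[scope_mask & (meta["condition"] == c).to_numpy()]
        rows[c] = coexpression_index(norm, gene_early, gene_late, cells,
                                     positivity_quantile)
    return pd.DataFrame(rows).T
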