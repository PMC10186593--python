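"""Ground-truthed synthetic scRNA-seq cohorts of the aging intestinal epithelium.

The generator emulates the statistical structure the downstream analyses
assume: four experimental groups (young ``Y``, old ``O``, old + metformin
``O_met``, old + rapamycin ``O_rap``) with a few mice each; a branching
stem -> enterocyte maturation continuum parameterized by a latent position
``s`` in [0, 1]; negative-binomial counts with log-normal library sizes and
per-mouse random intercepts; a stem-cell signature whose per-gene old/young
expression ratios are drawn from configurable six-compartment mixtures; and
pathway programs (Wnt, cell cycle, ribosome, OXPHOS) whose activity varies
along the continuum and shifts with condition.

Aging acts through a per-condition maturation delay ``delta``: the latent
boundaries at which the post-stem cell types emerge are shifted right by
``delta``, and stage-marker transitions broaden with ``delta`` so that
intermediate (co-expressing) states become more populated.  Drug conditions
partially undo both.

Condition ratios (the signature mixture and the Lgr5-like marker ratio) are
defined on the normalized-expression scale — the scale on which such ratios
are conventionally reported — and are converted internally to absolute rate
multipliers through a compositional closure factor (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CONDITIONS,
    MAIN_TYPES,
    MITO_PREFIX,
    PATHWAYS,
    CountMatrix,
    FixtureError,
    config_hash,
    read_mtx,
    read_tsv,
    write_gmt,
    write_mtx,
    write_tsv,
    read_gmt,
)

#: ratio-compartment bin edges, left-open / right-closed
COMPARTMENT_EDGES = (0.0, 0.5, 0.8, 1.0, 1.2, 1.5, np.inf)

#: upper cap used when sampling a ratio from the open top compartment
TOP_COMPARTMENT_CAP = 3.0

#: per-gene O/Y, O_met/Y, O_rap/Y compartment probabilities of the default
#: signature mixture (printed percentages; columns are normalized on use)
DEFAULT_SIGNATURE_MIXTURE = {
    "O": (0.12, 0.38, 0.21, 0.14, 0.10, 0.04),
    "O_met": (0.05, 0.30, 0.37, 0.17, 0.07, 0.04),
    "O_rap": (0.04, 0.33, 0.36, 0.17, 0.07, 0.02),
}

DEFAULT_DELAY = {"Y": 0.0, "O": 0.12, "O_met": 0.03, "O_rap": 0.05}

DEFAULT_LGR5_RATIO = {"O": 0.67, "O_met": 0.87, "O_rap": 0.83}

DEFAULT_PATHWAY_ACTIVITY = {
    "Wnt": {"Y": 1.0, "O": 0.70, "O_met": 0.90, "O_rap": 0.85},
    "CellCycle": {"Y": 1.0, "O": 0.75, "O_met": 0.95, "O_rap": 0.90},
    "Ribosome": {"Y": 1.0, "O": 1.30, "O_met": 1.25, "O_rap": 1.20},
    "Oxphos": {"Y": 1.0, "O": 1.40, "O_met": 1.10, "O_rap": 1.35},
}

PATHWAY_SIZES = {"Wnt": 60, "CellCycle": 80, "Ribosome": 90, "Oxphos": 90}

#: widths of the latent intervals occupied by the main cell types in young
#: mice (Stem, R, R-Div, Div1, Div2; EC takes the remainder)
TYPE_WIDTHS = (0.20, 0.14, 0.14, 0.14, 0.14)

N_MARKERS_PER_TYPE = 25
N_MARKERS_PER_SIDE = 20
N_MITO_GENES = 13
N_AXIS_GENES = 200


@dataclass
class SimConfig:
    """Parameters of a simulated cohort.  Defaults are the study conditions:
    4 groups x 3 mice, a 467-gene repressed stem signature with the default
    compartment mixture, an Lgr5-like marker repressed to 0.67 in old mice
    with partial drug reversal, and a delayed maturation continuum."""

    seed: int
    n_mice_per_condition: int = 3
    n_cells_per_mouse: int = 1000
    n_genes: int = 2000
    conditions: tuple = CONDITIONS
    delay_per_condition: dict = field(default_factory=lambda: dict(DEFAULT_DELAY))
    n_signature_genes: int = 467
    signature_ratio_mixture: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SIGNATURE_MIXTURE.items()}
    )
    reversal_epsilon: dict | None = None  # alt mode: r_c = 1 + eps_c * (r_O - 1)
    lgr5_ratio: dict = field(default_factory=lambda: dict(DEFAULT_LGR5_RATIO))
    pathway_activity: dict = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_PATHWAY_ACTIVITY.items()}
    )
    p_side: float = 0.15
    n_side_branches: int = 2
    mouse_effect_sd: float = 0.15
    nb_dispersion: float = 10.0
    library_size_mean: float = 5000.0
    library_size_log_sd: float = 0.3
    mito_share: float = 0.05
    transition_broadening: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_mice_per_condition, self.n_cells_per_mouse, self.n_genes) <= 0:
            raise ValueError("cohort dimensions must be positive")
        known = set(CONDITIONS)
        for c in self.conditions:
            if c not in known:
                raise ValueError(f"unknown condition label {c!r}; expected {CONDITIONS}")
        if "Y" not in self.conditions:
            raise ValueError("the reference condition 'Y' is required")
        for c in self.conditions:
            if self.delay_per_condition.get(c, 0.0) < 0:
                raise ValueError(f"delay for {c} must be >= 0")
        for p in PATHWAYS:
            if p not in self.pathway_activity:
                raise ValueError(f"missing pathway program {p!r} in pathway_activity")
            for c in self.conditions:
                if c not in self.pathway_activity[p]:
                    raise ValueError(f"pathway_activity[{p!r}] missing condition {c!r}")
        mix = {}
        for c, v in self.signature_ratio_mixture.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (6,):
                raise ValueError("compartment mixture needs exactly 6 entries")
            if (v < 0).any() or v.sum() <= 0:
                raise ValueError("compartment mixture must be non-negative, nonzero")
            v = v / v.sum()
            assert abs(v.sum() - 1.0) < 1e-12
            mix[c] = tuple(v)
        self.signature_ratio_mixture = mix
        required = self.n_signature_genes + 1 + sum(PATHWAY_SIZES.values()) + \
            len(MAIN_TYPES) * N_MARKERS_PER_TYPE + \
            self.n_side_branches * N_MARKERS_PER_SIDE + N_MITO_GENES + \
            N_AXIS_GENES + 2
        if self.n_genes < required + 10:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the configured programs "
                f"(need >= {required + 10})"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @property
    def type_boundaries(self) -> np.ndarray:
        """Young-mouse upper boundaries of Stem..Div2 on the latent axis."""
        return np.cumsum(TYPE_WIDTHS)


@dataclass
class GroundTruth:
    """Latent state used to generate a cohort; the yardstick for recovery tests."""

    cells: pd.DataFrame   # s, branch, cell_type per cell
    genes: pd.DataFrame   # program plus true per-condition ratio columns
    gene_sets: dict       # marker / pathway / signature GMT-style sets
    config: SimConfig


def compartment_of(ratios: np.ndarray) -> np.ndarray:
    """Compartment index 1-6 of each ratio under the (l, r] bin convention."""
    r = np.asarray(ratios, dtype=float)
    if (r <= 0).any():
        raise ValueError("ratios must be positive")
    inner = np.asarray(COMPARTMENT_EDGES[1:-1])
    return np.searchsorted(inner, r, side="left") + 1


def _sample_ratio(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    """Sample ratios: multinomial over the six compartments, uniform within."""
    lo = np.asarray(COMPARTMENT_EDGES[:-1])
    hi = np.asarray(COMPARTMENT_EDGES[1:]).copy()
    lo = lo.copy()
    lo[0] = 0.25  # avoid degenerate near-zero rates in the bottom bin
    hi[-1] = TOP_COMPARTMENT_CAP
    bins = rng.choice(6, size=size, p=probs)
    return rng.uniform(lo[bins], hi[bins])


def _build_gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign gene names, programs and baseline rates (expected counts in a
    cell of library size ``library_size_mean`` before profile effects)."""
    names, program, base = [], [], []

    def add(n, name_fn, prog, scale):
        for i in range(n):
            names.append(name_fn(i))
            program.append(prog)
        base.extend(scale * rng.lognormal(-0.32, 0.8, size=n))  # mean ~ scale

    add(cfg.n_signature_genes, lambda i: f"Sig{i + 1:04d}", "signature", 2.0)
    names.append("Lgr5")
    program.append("lgr5")
    base.append(3.0)
    for t in MAIN_TYPES:
        add(N_MARKERS_PER_TYPE, lambda i, t=t: f"Mk{t.replace('-', '')}_{i + 1:02d}",
            f"marker_{t}", 0.5)
    for k in range(cfg.n_side_branches):
        add(N_MARKERS_PER_SIDE, lambda i, k=k: f"MkSide{k + 1}_{i + 1:02d}",
            f"marker_Side{k + 1}", 0.5)
    add(N_AXIS_GENES, lambda i: f"Axis{i + 1:02d}", "axis", 2.0)
    names.append("Uhrf1")
    program.append("coexpr_early")
    base.append(1.0)
    names.append("Ccnb1")
    program.append("coexpr_late")
    base.append(1.0)
    for p in PATHWAYS:
        add(PATHWAY_SIZES[p], lambda i, p=p: f"{p}_{i + 1:03d}", f"pathway_{p}", 2.0)
    mito_names = [f"{MITO_PREFIX}Gene{i + 1:02d}" for i in range(N_MITO_GENES)]
    names.extend(mito_names)
    program.extend(["mito"] * N_MITO_GENES)
    base.extend(np.ones(N_MITO_GENES))  # rescaled to mito_share below
    n_bg = cfg.n_genes - len(names)
    add(n_bg, lambda i: f"Bg{i + 1:04d}", "background", 1.0)

    base = np.asarray(base)
    is_mito = np.asarray([p == "mito" for p in program])
    other = base[~is_mito].sum()
    base[is_mito] = cfg.mito_share / (1 - cfg.mito_share) * other / N_MITO_GENES
    return pd.DataFrame({"program": program, "base_rate": base},
                        index=pd.Index(names, name="gene"))


def _pathway_profile(pathway: str, s: np.ndarray) -> np.ndarray:
    """Latent-position activity profile of each pathway program (young shape)."""
    if pathway == "Wnt":
        return 1.0 + 2.5 * np.exp(-((s / 0.22) ** 2))
    if pathway == "CellCycle":
        return 1.0 + 3.0 * np.exp(-(((s - 0.45) / 0.18) ** 2) / 2)
    if pathway == "Ribosome":
        return 1.0 + 2.0 * np.exp(-s / 0.30)
    if pathway == "Oxphos":
        return 1.0 + 2.5 * np.exp(-(((s - 0.55) / 0.20) ** 2) / 2)
    raise ValueError(f"unknown pathway {pathway!r}")


def _type_of(s: np.ndarray, delta: float, boundaries: np.ndarray) -> np.ndarray:
    """Cell type from latent position; post-stem boundaries delayed by delta."""
    idx = np.searchsorted(boundaries + delta, s, side="right")
    return np.asarray(MAIN_TYPES)[idx]


def _marker_activity(s: np.ndarray, lo: float, hi: float, delta: float,
                     broaden: float, anchored_low: bool = False) -> np.ndarray:
    """Gaussian stage bump over the delay-shifted type interval.

    The interval [lo, hi] shifts right by ``delta`` (its lower end stays at 0
    for the stem interval, which stretches rather than moves) and its width
    broadens with ``delta`` — delayed and blurred stage transitions.
    """
    lo2 = lo if anchored_low else lo + delta
    hi2 = hi + delta
    center = (lo2 + hi2) / 2
    sigma = (hi2 - lo2) / 2.8 * (1 + broaden * delta)
    return np.exp(-(((s - center) / sigma) ** 2) / 2)


def _plateau_activity(s: np.ndarray, lo: float, hi: float, delta: float,
                      broaden: float, tau: float = 0.05) -> np.ndarray:
    """Flat-top activation over [lo, hi] (delay-shifted) with sigmoid edges
    whose softness grows with the delay."""
    t = tau * (1 + broaden * delta)
    lo2, hi2 = lo + delta, hi + delta
    return 1.0 / (1 + np.exp(-(s - lo2) / t)) / (1 + np.exp(-(hi2 - s) / t))


def _true_ratios(cfg: SimConfig, rng: np.random.Generator,
                 genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene true condition/Y ratio on the normalized-expression scale."""
    ratios = pd.DataFrame(1.0, index=genes.index,
                          columns=[c for c in cfg.conditions if c != "Y"])
    sig = genes.index[genes["program"] == "signature"]
    r_old = None
    for c in ratios.columns:
        if cfg.reversal_epsilon is not None and c in cfg.reversal_epsilon:
            if r_old is None:
                raise ValueError("reversal_epsilon requires condition 'O' first")
            ratios.loc[sig, c] = 1 + cfg.reversal_epsilon[c] * (r_old - 1)
        elif c in cfg.signature_ratio_mixture:
            probs = np.asarray(cfg.signature_ratio_mixture[c])
            ratios.loc[sig, c] = _sample_ratio(rng, probs, len(sig))
        if c == "O":
            r_old = ratios.loc[sig, c].to_numpy().copy()
        if c in cfg.lgr5_ratio:
            ratios.loc["Lgr5", c] = cfg.lgr5_ratio[c]
        for p in PATHWAYS:
            ratios.loc[genes["program"] == f"pathway_{p}", c] = \
                cfg.pathway_activity[p][c] / cfg.pathway_activity[p]["Y"]
    return ratios


def _sample_latent(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Latent per-cell state: position s, branch, delayed cell type."""
    boundaries = cfg.type_boundaries
    cell_rows = []
    for cond in cfg.conditions:
        for m in range(cfg.n_mice_per_condition):
            mouse = f"{cond}{m + 1}"
            s = rng.uniform(0, 1, cfg.n_cells_per_mouse)
            on_side = rng.uniform(size=cfg.n_cells_per_mouse) < cfg.p_side
            branch_k = rng.integers(1, cfg.n_side_branches + 1,
                                    cfg.n_cells_per_mouse)
            # side branches are localized: branch k leaves the main route
            # near a type boundary on the latent axis
            bd = np.asarray(boundaries)
            attach = bd[(2 * branch_k - 1) % len(bd)]
            s = np.where(on_side,
                         np.clip(attach + (s - 0.5) * 0.2, 0, 1), s)
            delta = cfg.delay_per_condition.get(cond, 0.0)
            ctype = _type_of(s, delta, boundaries)
            for j in range(cfg.n_cells_per_mouse):
                cell_rows.append((
                    f"{mouse}_c{j + 1:05d}", mouse, cond, s[j],
                    f"side_{branch_k[j]}" if on_side[j] else "main", ctype[j],
                ))
    return pd.DataFrame(
        cell_rows, columns=["cell", "mouse", "condition", "s", "branch",
                            "cell_type"]).set_index("cell")


def sample_latent_cohort(config: SimConfig) -> pd.DataFrame:
    """Latent cohort only (no counts): per-cell mouse, condition, latent
    position s, branch and delayed cell type.  Useful for cheap calibration
    studies of the trajectory statistics at many replicates."""
    return _sample_latent(config, np.random.default_rng(config.seed))


def generate_cohort(config: SimConfig):
    """Simulate a cohort.

    Returns ``(counts, meta, truth)`` where ``counts`` is a
    :class:`~iscaging.io.CountMatrix`, ``meta`` its per-cell metadata frame
    (mouse, condition) and ``truth`` the :class:`GroundTruth` used to
    generate it.  Same config + same seed is bit-reproducible.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _build_gene_table(cfg, rng)
    ratio_cols = _true_ratios(cfg, rng, genes)
    boundaries = cfg.type_boundaries
    broaden = cfg.transition_broadening

    # monotone crypt-villus axis slopes (half increasing, half decreasing)
    axis_slope = rng.uniform(2.0, 4.0, N_AXIS_GENES) * \
        np.where(np.arange(N_AXIS_GENES) % 2 == 0, 1.0, -1.0)

    cells = _sample_latent(cfg, rng)
    s_all = cells["s"].to_numpy()
    side_all = np.where(cells["branch"] == "main", 0,
                        cells["branch"].str.removeprefix("side_")
                        .where(cells["branch"] != "main", "0").astype(int))

    # --- compose per-cell rates (genes x cells), in per-mouse blocks
    base = genes["base_rate"].to_numpy()
    prog = genes["program"].to_numpy()
    n_cells = len(cells)
    rates = np.empty((cfg.n_genes, n_cells))
    type_lims = np.concatenate([[0.0], boundaries, [1.0]])
    cond_of_cell = cells["condition"].to_numpy()
    for cond in cfg.conditions:
        colmask = cond_of_cell == cond
        s = s_all[colmask]
        side = side_all[colmask]
        delta = cfg.delay_per_condition.get(cond, 0.0)
        block = np.repeat(base[:, None], colmask.sum(), axis=1)
        # stage markers: Gaussian bump over the type interval, damped on side cells
        stage_damp = np.where(side > 0, 0.3, 1.0)
        for t_idx, t in enumerate(MAIN_TYPES):
            act = _marker_activity(s, type_lims[t_idx], type_lims[t_idx + 1],
                                   delta, broaden, anchored_low=(t_idx == 0))
            gmask = prog == f"marker_{t}"
            block[gmask] *= 1 + 18.0 * act * stage_damp
        # side-branch markers: flat, on for the branch's cells only
        for k in range(1, cfg.n_side_branches + 1):
            gmask = prog == f"marker_Side{k}"
            block[gmask] *= np.where(side == k, 19.0, 1.0)
        # co-expression pair: early- and late-progenitor plateau programs
        # with overlapping soft edges; the overlap zone holds the
        # transitioning (co-expressing) cells and widens with the delay
        grow = 0.5 * broaden * delta  # transition zone widens with the delay
        for name, lo, hi in (
                ("Uhrf1", type_lims[1] - 0.02, type_lims[3] + 0.05 + grow),
                ("Ccnb1", type_lims[3] - 0.05 - grow, type_lims[5] + 0.02)):
            act = _plateau_activity(s, lo, hi, delta, broaden)
            block[genes.index.get_loc(name)] *= 1 + 16.0 * act
        # cells inside the early->late hand-off zone transiently co-express
        # both programs; the zone (and hence the co-positive pool) widens
        # with the maturation delay
        zone_c = type_lims[3] + delta
        zone_half = 0.008 + 0.4 * broaden * delta * 0.1
        in_zone = np.abs(s - zone_c) < zone_half
        co_boost = np.where(in_zone, rng.lognormal(0.7, 0.5, s.size), 1.0)
        for name in ("Uhrf1", "Ccnb1"):
            block[genes.index.get_loc(name)] *= co_boost
        # crypt-villus axis genes: monotone positional gradients.  These are
        # deliberately not delay-shifted: aging delays the identity and
        # pathway programs relative to the cell's position along the axis,
        # which is what makes the maturation delay observable.
        gmask = prog == "axis"
        block[gmask] *= np.exp(axis_slope[:, None] * (s - 0.5)[None, :])
        # pathway programs: positional profile shape (not delay-shifted)
        # times the per-condition activity multiplier
        for p in PATHWAYS:
            gmask = prog == f"pathway_{p}"
            mult = cfg.pathway_activity[p][cond] / cfg.pathway_activity[p]["Y"]
            block[gmask] *= _pathway_profile(p, s) * mult
        # signature + Lgr5 condition ratios (closure-corrected below)
        if cond != "Y":
            gmask = (prog == "signature") | (prog == "lgr5")
            block[gmask] *= ratio_cols.loc[gmask, cond].to_numpy()[:, None]
        rates[:, colmask] = block

    # --- compositional closure.  The configured ratios are defined on the
    # normalized-expression scale (the scale on which such ratios are
    # reported), and per-cell mRNA content is taken as condition-invariant:
    # condition effects redistribute the transcriptome rather than change
    # its total.  Hence (i) the non-ratio part of every cell's rate vector
    # is normalized to a constant total, and (ii) the ratio-carrying genes
    # (signature + Lgr5-like marker, flat along the continuum) are rescaled
    # per condition so their pooled rate mass matches the reference, making
    # the normalized-scale ratio of every such gene equal its configured
    # truth in expectation.
    ratio_genes = (prog == "signature") | (prog == "lgr5")
    nonratio_sum = rates[~ratio_genes].sum(axis=0)
    n_const = nonratio_sum.mean()
    rates[~ratio_genes] *= n_const / nonratio_sum
    s_y = rates[np.ix_(ratio_genes, cond_of_cell == "Y")].sum(axis=0).mean()
    for cond in cfg.conditions:
        if cond == "Y":
            continue
        colmask = cond_of_cell == cond
        s_c = rates[np.ix_(ratio_genes, colmask)].sum(axis=0).mean()
        # solves  r * g * T_Y / (N + g * S_c) = r  with T_Y = N + S_Y
        rates[np.ix_(ratio_genes, colmask)] *= n_const / (n_const + s_y - s_c)

    # --- library sizes, mouse random intercepts, NB sampling
    rates /= rates.sum(axis=0).mean()
    log_ls = np.log(cfg.library_size_mean) - cfg.library_size_log_sd ** 2 / 2
    libsize = rng.lognormal(log_ls, cfg.library_size_log_sd, n_cells)
    mice = cells["mouse"].unique()
    m_eff = dict(zip(mice, rng.lognormal(
        -cfg.mouse_effect_sd ** 2 / 2, cfg.mouse_effect_sd, len(mice))))
    cell_eff = cells["mouse"].map(m_eff).to_numpy()
    mu = rates * (libsize * cell_eff)[None, :]
    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int32)

    meta = cells[["mouse", "condition"]].copy()
    counts_m = CountMatrix(sp.csr_matrix(counts), genes[["program"]].copy(), meta)

    gene_truth = genes[["program"]].copy()
    for c in ratio_cols.columns:
        gene_truth[f"ratio_{c}"] = ratio_cols[c]
    gene_sets = {f"Marker_{t}": list(genes.index[prog == f"marker_{t}"])
                 for t in MAIN_TYPES}
    for k in range(1, cfg.n_side_branches + 1):
        gene_sets[f"Marker_Side{k}"] = list(genes.index[prog == f"marker_Side{k}"])
    for p in PATHWAYS:
        gene_sets[p] = list(genes.index[prog == f"pathway_{p}"])
    gene_sets["Lgr5_signature"] = list(genes.index[prog == "signature"])
    truth = GroundTruth(cells=cells[["s", "branch", "cell_type"]].copy(),
                        genes=gene_truth, gene_sets=gene_sets, config=cfg)
    return counts_m, meta, truth


# ---------------------------------------------------------------------------
# fixture round-trip

def write_fixture(counts: CountMatrix, truth: GroundTruth | None, directory) -> dict:
    """Write a cohort as plain-text files; returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = truth.config if truth is not None else None
    seed = cfg.seed if cfg is not None else 0
    chash = config_hash(cfg.to_dict()) if cfg is not None else ""
    paths = {
        "counts": d / "counts.mtx",
        "genes": d / "genes.tsv",
        "cells": d / "cells.tsv",
    }
    write_mtx(counts.counts, paths["counts"], seed=seed, cfg_hash=chash)
    write_tsv(counts.genes, paths["genes"], seed=seed, cfg_hash=chash,
              index_label="gene")
    write_tsv(counts.cells, paths["cells"], seed=seed, cfg_hash=chash,
              index_label="cell")
    if truth is not None:
        paths["truth_cells"] = d / "truth_cells.tsv"
        paths["truth_genes"] = d / "truth_genes.tsv"
        paths["config"] = d / "config.json"
        paths["gene_sets"] = d / "gene_sets.gmt"
        write_tsv(truth.cells, paths["truth_cells"], seed=seed, cfg_hash=chash,
                  index_label="cell")
        write_tsv(truth.genes, paths["truth_genes"], seed=seed, cfg_hash=chash,
                  index_label="gene")
        paths["config"].write_text(json.dumps(
            {"config": cfg.to_dict(), "config_sha": chash}, indent=2))
        write_gmt(truth.gene_sets, paths["gene_sets"])
    return {k: str(v) for k, v in paths.items()}


def read_fixture(directory):
    """Read a cohort written by :func:`write_fixture`.

    Returns ``(counts, truth_or_None)``; validates dimensional agreement
    between the matrix and the metadata tables.
    """
    d = Path(directory)
    counts = read_mtx(d / "counts.mtx")
    genes = read_tsv(d / "genes.tsv")
    cells = read_tsv(d / "cells.tsv")
    if counts.shape[0] != len(genes):
        raise FixtureError(
            f"{d / 'genes.tsv'}: {len(genes)} rows but matrix has "
            f"{counts.shape[0]} gene rows")
    if counts.shape[1] != len(cells):
        raise FixtureError(
            f"{d / 'cells.tsv'}: {len(cells)} rows but matrix has "
            f"{counts.shape[1]} cell columns")
    cm = CountMatrix(counts, genes, cells)
    truth = None
    if (d / "config.json").exists():
        payload = json.loads((d / "config.json").read_text())
        cfg_d = payload["config"]
        cfg_d["conditions"] = tuple(cfg_d["conditions"])
        cfg = SimConfig(**cfg_d)
        truth = GroundTruth(
            cells=read_tsv(d / "truth_cells.tsv"),
            genes=read_tsv(d / "truth_genes.tsv"),
            gene_sets=read_gmt(d / "gene_sets.gmt"),
            config=cfg,
        )
    return cm, truth
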