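"""End-to-end orchestration: simulate -> preprocess -> DE -> score -> GSEA ->
trajectory -> stats, with a machine-readable JSON report and a Markdown
summary.

A single global seed deterministically derives per-stage seeds (CRC32 of
the stage name), so stages are reproducible in isolation and the whole
report is byte-identical across reruns of the same config.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr as de
from . import gsea as gsea_mod
from . import preprocess as pp
from . import scoring
from . import trajectory as traj_mod
from .io import (CONDITIONS, CountMatrix, FixtureError, config_hash, read_gmt,
                 read_mtx, read_tsv, write_tsv)
from .stats import anova_tukey
from .synthetic_data import SimConfig, generate_cohort, read_fixture, write_fixture

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "diffexpr", "score", "gsea",
          "trajectory", "stats")

#: stage -> stages it needs
DEPENDENCIES = {
    "preprocess": (),
    "diffexpr": ("preprocess",),
    "score": ("preprocess",),
    "gsea": ("diffexpr",),
    "trajectory": ("preprocess", "score"),
    "stats": ("score",),
}

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "results/run",
    "log_level": "INFO",
    "write_fixture": False,
    "stages": {s: True for s in STAGES},
    "input": {"fixture_dir": None},
    "simulate": {},
    "preprocess": {"min_genes": 200, "max_genes": 5000,
                   "max_mito_fraction": 0.20, "n_components": 30,
                   "n_neighbors": 15, "resolution": 2.5, "n_top_genes": 2000},
    "diffexpr": {"method": "pseudobulk", "contrasts": [["O", "Y"]],
                 "clusters": "all", "adjust": "bh",
                 "fc_threshold": 1.5, "padj_threshold": 0.01},
    "score": {"n_bins": 24, "n_ctrl": 100,
              "ratio_contrasts": ["O", "O_met", "O_rap"]},
    "gsea": {"n_perm": 2000, "weight": 1.0},
    "trajectory": {"root": "Stem", "terminus": "EC", "q_emergence": 0.05,
                   "positivity_quantile": 0.96,
                   "coexpression_pair": ["Uhrf1", "Ccnb1"]},
}


def stage_seed(global_seed: int, stage: str) -> int:
    return int((global_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31))


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _merge(cfg, user)
    if overrides:
        _merge(cfg, overrides)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def check_dependencies(cfg: dict) -> None:
    stages = cfg["stages"]
    has_input = cfg["input"].get("fixture_dir") is not None
    for s in STAGES:
        if not stages.get(s):
            continue
        if s == "simulate":
            continue
        if s == "preprocess" and not (stages.get("simulate") or has_input):
            raise ValueError("preprocess enabled but neither simulate nor an "
                             "input fixture_dir is configured")
        for dep in DEPENDENCIES.get(s, ()):
            if not stages.get(dep):
                raise ValueError(f"stage {s!r} requires disabled stage {dep!r}")


@dataclass
class RunReport:
    report: dict
    outdir: Path

    def table(self, name: str):
        return self.report["tables"].get(name)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: dict | str | Path | None = None) -> RunReport:
    """Execute the enabled stages in dependency order; returns the report."""
    cfg = config if isinstance(config, dict) else load_config(config)
    check_dependencies(cfg)
    logging.basicConfig(level=getattr(logging, cfg.get("log_level", "INFO")))
    seed = int(cfg["seed"])
    chash = config_hash(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    status: dict[str, str] = {}
    tables: dict[str, object] = {}
    state: dict[str, object] = {}

    def run_stage(name, fn):
        if not stages.get(name):
            status[name] = "skipped"
            return
        try:
            fn()
            status[name] = "ok"
        except Exception as exc:
            status[name] = f"failed: {exc}"
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # ------------------------------------------------------------- simulate
    def do_simulate():
        sim_cfg = SimConfig(seed=stage_seed(seed, "simulate"),
                            **cfg.get("simulate", {}))
        counts, meta, truth = generate_cohort(sim_cfg)
        state.update(counts=counts, meta=meta, truth=truth,
                     gene_sets=truth.gene_sets)
        if cfg.get("write_fixture"):
            write_fixture(counts, truth, outdir / "fixture")

    run_stage("simulate", do_simulate)

    if "counts" not in state and cfg["input"].get("fixture_dir"):
        counts, truth = read_fixture(cfg["input"]["fixture_dir"])
        state.update(counts=counts, meta=counts.cells, truth=truth,
                     gene_sets=truth.gene_sets if truth else {})

    # ----------------------------------------------------------- preprocess
    def do_preprocess():
        p = cfg["preprocess"]
        thr = pp.QCThresholds(p["min_genes"], p["max_genes"],
                              p["max_mito_fraction"])
        kept, removal = pp.qc_filter(state["counts"], thr)
        norm = pp.normalize(kept)
        emb = pp.embed(norm, n_components=p["n_components"],
                       n_top_genes=p["n_top_genes"])
        labels = pp.cluster(emb, n_neighbors=p["n_neighbors"],
                            resolution=p["resolution"],
                            seed=stage_seed(seed, "cluster"))
        marker_sets = {k: v for k, v in state["gene_sets"].items()
                       if k.startswith("Marker_")}
        marker_sets = {k.removeprefix("Marker_"): v
                       for k, v in marker_sets.items()}
        types, props = pp.annotate_types(norm, labels, marker_sets)
        meta = norm.cells.copy()
        meta["cluster"] = labels
        meta["cell_type"] = types
        norm.cells = meta
        state.update(kept=kept, norm=norm, embedding=emb, meta=meta)
        tables["qc"] = {"n_cells_in": int(state["counts"].n_cells),
                        "n_removed": int(len(removal)),
                        "n_kept": int(kept.n_cells)}
        tables["type_proportions"] = (props.round(6).to_dict()
                                      if props is not None else None)
        write_tsv(meta, outdir / "cell_metadata.tsv", seed, chash,
                  index_label="cell")

    run_stage("preprocess", do_preprocess)

    # ------------------------------------------------------------- diffexpr
    def do_diffexpr():
        d = cfg["diffexpr"]
        meta = state["meta"]
        kept: CountMatrix = state["kept"]
        totals = np.asarray(kept.counts.sum(axis=0)).ravel()
        clusters = (sorted(meta["cell_type"].unique().tolist())
                    if d["clusters"] == "all" else d["clusters"])
        frames = []
        for cl in clusters:
            for contrast in d["contrasts"]:
                test_lvl, ref_lvl = contrast
                mask = ((meta["cell_type"] == cl)
                        & meta["condition"].isin([test_lvl, ref_lvl])).to_numpy()
                if mask.sum() < 10:
                    continue
                frames.append(de.de_table(
                    kept, meta, totals, mask, (test_lvl, ref_lvl),
                    method=d["method"], cluster=cl, adjust=d["adjust"]))
        results = pd.concat(frames)
        deg_counts, excluded = de.count_degs(
            results, d["fc_threshold"], d["padj_threshold"])
        state["de_results"] = results
        tables["deg_counts"] = deg_counts.to_dict(orient="records")
        tables["de_non_converged"] = sorted(set(excluded))
        write_tsv(results, outdir / "de_results.tsv", seed, chash,
                  index_label="gene")
        write_tsv(deg_counts, outdir / "deg_counts.tsv", seed, chash,
                  index=False)

    run_stage("diffexpr", do_diffexpr)

    # ---------------------------------------------------------------- score
    def do_score():
        sc = cfg["score"]
        norm = state["norm"]
        meta = state["meta"]
        gene_sets = state["gene_sets"]
        pathway_sets = {k: gene_sets[k] for k in
                        ("Wnt", "CellCycle", "Ribosome", "Oxphos")
                        if k in gene_sets}
        scores = scoring.score_gene_sets(norm, pathway_sets,
                                         n_bins=sc["n_bins"],
                                         n_ctrl=sc["n_ctrl"],
                                         seed=stage_seed(seed, "score"))
        state["module_scores"] = scores
        stem_cells = meta.index[meta["cell_type"] == "Stem"]
        by_mouse, by_cond = scoring.mean_score_by_mouse(scores, meta,
                                                        scope=stem_cells)
        state["stem_mouse_scores"] = by_mouse
        tables["stem_module_scores_by_condition"] = by_cond.round(6).to_dict()
        write_tsv(scores, outdir / "module_scores.tsv", seed, chash,
                  index_label="cell")
        # signature ratio compartments in the Stem cluster
        signature = gene_sets.get("Lgr5_signature", [])
        summary = {}
        ratio_tables = {}
        if signature:
            means = scoring.mean_expression_by_condition(
                norm, meta, "Stem", signature)
            for contrast in sc["ratio_contrasts"]:
                if contrast not in means.columns:
                    continue
                rt = scoring.expression_ratio(means, contrast, "Y")
                vec, below1 = scoring.compartment_summary(rt)
                summary[f"{contrast}/Y"] = {
                    "compartments": vec.round(4).tolist(),
                    "pct_below_1": round(below1, 4),
                    "n_genes": int(len(rt.table)),
                }
                ratio_tables[contrast] = rt
            state["ratio_tables"] = ratio_tables
        if "Lgr5" in norm.gene_ids:
            lgr5 = scoring.mean_expression_by_condition(norm, meta, "Stem",
                                                        ["Lgr5"])
            tables["lgr5_stem_mean"] = lgr5.round(6).loc["Lgr5"].to_dict()
        tables["signature_compartments"] = summary

    run_stage("score", do_score)

    # ----------------------------------------------------------------- gsea
    def do_gsea():
        g = cfg["gsea"]
        results = state["de_results"]
        stem = results[(results["cluster"] == "Stem")
                       & (results["converged"] == "ok")]
        first_contrast = stem["contrast"].iloc[0]
        stem = stem[stem["contrast"] == first_contrast]
        ranked = gsea_mod.rank_genes(stem)
        pathway_sets = {k: state["gene_sets"][k] for k in
                        ("Wnt", "CellCycle", "Ribosome", "Oxphos")
                        if k in state["gene_sets"]}
        table = gsea_mod.gsea_permutation(ranked, pathway_sets,
                                          n_perm=g["n_perm"],
                                          weight=g["weight"],
                                          seed=stage_seed(seed, "gsea"))
        tables["gsea"] = (table.drop(columns=["leading_edge"])
                          .round(6).reset_index().to_dict(orient="records"))
        write_tsv(table, outdir / "gsea_results.tsv", seed, chash,
                  index_label="set")

    run_stage("gsea", do_gsea)

    # ------------------------------------------------------------ trajectory
    def do_trajectory():
        t = cfg["trajectory"]
        meta = state["meta"]
        emb = state["embedding"]
        graph = traj_mod.learn_trajectory(emb.coords, meta["cell_type"],
                                          t["root"])
        dichotomy = traj_mod.select_and_dichotomize(graph, t["terminus"])
        meta["dichotomy"] = dichotomy
        meta["pseudotime"] = graph.pseudotime
        state["trajectory"] = graph
        selected = dichotomy != "excluded"
        part = traj_mod.CompartmentPartition.tertiles(
            graph.pseudotime[selected & (dichotomy == "main")])
        per_comp, joint = traj_mod.compartment_transition_test(
            meta.loc[selected, "cell_type"],
            graph.pseudotime[selected],
            part, meta.loc[selected, "condition"],
            seed=stage_seed(seed, "transition"))
        tables["compartment_transition"] = {
            **{k: v.to_dict() for k, v in per_comp.items()},
            "joint": joint.to_dict(),
        }
        delays = traj_mod.emergence_delay(
            meta.loc[selected, "cell_type"], graph.pseudotime[selected],
            dichotomy[selected], meta.loc[selected, "condition"],
            q=t["q_emergence"])
        tables["emergence_delay"] = delays.round(6).to_dict()
        profiles = {}
        for pw in ("Oxphos", "CellCycle"):
            if pw in state.get("module_scores", pd.DataFrame()).columns:
                prof = traj_mod.branchpoint_module_profile(
                    state["module_scores"][pw], graph, t["terminus"],
                    meta["condition"])
                profiles[pw] = prof.round(6).to_dict()
        tables["branchpoint_profiles"] = profiles
        early, late = t["coexpression_pair"]
        prog_types = ("R", "R-Div", "Div1", "Div2")
        scope = (meta["cell_type"].isin(prog_types)
                 & (dichotomy == "main")).to_numpy()
        if scope.any() and early in state["norm"].gene_ids.tolist():
            coex = traj_mod.coexpression_by_condition(
                state["norm"], meta, early, late, scope,
                t["positivity_quantile"])
            tables["coexpression_index"] = coex.round(6).to_dict()
        write_tsv(meta[["cluster", "cell_type", "condition", "mouse",
                        "pseudotime", "dichotomy"]],
                  outdir / "trajectory_cells.tsv", seed, chash,
                  index_label="cell")

    run_stage("trajectory", do_trajectory)

    # ---------------------------------------------------------------- stats
    def do_stats():
        meta = state["meta"]
        scores = state["module_scores"]
        out = {}
        # per-pathway ANOVA across conditions for main vs side cells
        if "dichotomy" in meta.columns:
            for arm in ("main", "side"):
                mask = (meta["dichotomy"] == arm).to_numpy()
                if mask.sum() < 8:
                    continue
                for pw in scores.columns:
                    res, tukey = anova_tukey(scores.loc[mask, pw],
                                             meta.loc[mask, "condition"])
                    out[f"{arm}:{pw}"] = {
                        **res.to_dict(),
                        "tukey": tukey.round(6).to_dict(orient="records"),
                    }
        tables["anova_main_side"] = out
        # KS between ratio distributions (drug rescue of the signature)
        ks_out = {}
        rts = state.get("ratio_tables", {})
        if "O" in rts:
            for drug in ("O_met", "O_rap"):
                if drug in rts:
                    r = scoring.compare_ratio_distributions(rts["O"], rts[drug])
                    ks_out[f"O_vs_{drug}"] = r.to_dict()
            if "O_met" in rts and "O_rap" in rts:
                ks_out["O_met_vs_O_rap"] = scoring.compare_ratio_distributions(
                    rts["O_met"], rts["O_rap"]).to_dict()
        tables["ks_ratio_distributions"] = ks_out
        # bivariate pathway coordination (mouse means, Stem scope)
        biv = {}
        mouse_means = state.get("stem_mouse_scores")
        if mouse_means is not None:
            for a, b in (("Wnt", "CellCycle"), ("Ribosome", "CellCycle")):
                if a in mouse_means.columns and b in mouse_means.columns:
                    res, ell = scoring.bivariate_coordination(mouse_means, a, b)
                    biv[f"{a}~{b}"] = {**res.to_dict(), "ellipses": ell}
        tables["bivariate_manova"] = biv

    run_stage("stats", do_stats)

    report = {
        "seed": seed,
        "config_sha": chash,
        "config": cfg,
        "status": status,
        "tables": _round_floats(tables),
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n")
    (outdir / "report.md").write_text(_markdown_summary(report))
    return RunReport(report=report, outdir=outdir)


def _markdown_summary(report: dict) -> str:
    lines = ["# Pipeline run summary", "",
             f"- seed: {report['seed']}",
             f"- config hash: {report['config_sha']}", "", "## Stages", ""]
    for s, v in report["status"].items():
        lines.append(f"- {s}: {v}")
    t = report["tables"]
    if t.get("qc"):
        lines += ["", "## QC", "",
                  f"kept {t['qc']['n_kept']} of {t['qc']['n_cells_in']} cells "
                  f"({t['qc']['n_removed']} removed)"]
    if t.get("signature_compartments"):
        lines += ["", "## Signature ratio compartments (% per bin)", ""]
        for contrast, d in t["signature_compartments"].items():
            comp = ", ".join(f"{x:.1f}" for x in d["compartments"])
            lines.append(f"- {contrast}: [{comp}]  below-1: "
                         f"{d['pct_below_1']:.1f}% (n={d['n_genes']})")
    if t.get("deg_counts"):
        lines += ["", "## DEG counts", ""]
        for rec in t["deg_counts"]:
            lines.append(f"- {rec['cluster']} {rec['contrast']}: "
                         f"{rec['n_degs']} of {rec['n_tested']}")
    if t.get("gsea"):
        lines += ["", "## GSEA (stem cluster)", ""]
        for rec in t["gsea"]:
            lines.append(f"- {rec['set']}: NES={rec['nes']}, p_adj={rec['p_adj']}")
    if t.get("emergence_delay"):
        lines += ["", "## Emergence delay vs Y (pseudotime units)", ""]
        for col, d in t["emergence_delay"].items():
            if col.startswith("delay_"):
                row = ", ".join(f"{k}: {v}" for k, v in d.items())
                lines.append(f"- {col}: {row}")
    if t.get("coexpression_index"):
        lines += ["", "## Co-expression index (early/late pair)", ""]
        for cond, d in t["coexpression_index"].get("index", {}).items() \
                if "index" in t["coexpression_index"] else []:
            lines.append(f"- {cond}: {d}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# input validation

def validate_inputs(paths: dict) -> list:
    """Check fixture conformance; returns a list of findings (empty = clean)."""
    findings = []
    counts = None
    if "counts" in paths:
        try:
            counts = read_mtx(paths["counts"])
        except FixtureError as exc:
            findings.append(str(exc))
    for key, axis in (("genes", 0), ("cells", 1)):
        if key not in paths:
            continue
        try:
            df = read_tsv(paths[key])
        except Exception as exc:
            findings.append(f"{paths[key]}: unreadable ({exc})")
            continue
        if counts is not None and len(df) != counts.shape[axis]:
            findings.append(
                f"{paths[key]}: {len(df)} rows vs matrix axis {axis} size "
                f"{counts.shape[axis]}")
        if key == "cells" and "condition" in df.columns:
            unknown = sorted(set(df["condition"]) - set(CONDITIONS))
            if unknown:
                findings.append(
                    f"{paths[key]}: unknown condition labels {unknown}; "
                    f"expected one of {list(CONDITIONS)}")
    if "gene_sets" in paths:
        for lineno, line in enumerate(
                Path(paths["gene_sets"]).read_text().splitlines(), start=1):
            if line.strip() and len(line.split("\t")) < 3:
                findings.append(
                    f"{paths['gene_sets']}:{lineno}: GMT line has fewer than "
                    "3 tab-separated fields")
    return findings
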