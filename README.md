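# iscaging

Single-cell analysis of intestinal stem-cell aging and its partial reversal
by geroprotectors (metformin, rapamycin), packaged as a tested, reusable
pipeline with a ground-truthed synthetic cohort generator.

Aging represses the transcriptional program of Lgr5-high intestinal stem
cells and delays the maturation of their progeny along the stem →
enterocyte trajectory.  This package re-implements the quantitative core of
that analysis for a four-group design (young `Y`, old `O`, old + metformin
`O_met`, old + rapamycin `O_rap`, 3 mice each):

* **Signature ratio compartments** — per-gene condition/young expression
  ratios of a stem-cell signature (467 genes by default), summarized over
  six fixed compartments (0–0.5, 0.5–0.8, 0.8–1, 1–1.2, 1.2–1.5, >1.5) and
  compared across conditions with the two-sample Kolmogorov–Smirnov test.
* **Module scores** — control-bin gene-set scoring (per-cell mean of the
  set minus expression-matched random controls) for Wnt, cell-cycle,
  ribosome and OXPHOS programs, with per-mouse averaging and a bivariate
  MANOVA (Pillai trace) of pathway coordination.
* **Differential expression** — a per-gene negative-binomial mixed model:
  cell counts with log link, offset log(total counts), fixed condition
  effects and a Gaussian per-mouse random intercept integrated by Laplace
  approximation (`y_gi ~ NB(exp(log T_i + x_i'β + u_m(i)), θ_g)`,
  `u_m ~ N(0, σ²)`), plus a fast mouse-level pseudobulk NB fallback; DEGs
  counted at |FC| ≥ 1.5 and adjusted p < 0.01.
* **Preranked GSEA** — the classic weighted running-sum enrichment score on
  the DE fold-change ranking, gene-label permutation null, NES and BH
  adjustment.
* **Trajectory** — a deterministic principal graph (minimum spanning tree
  over cluster medoids in PCA space) with per-cell pseudotime, main/side
  dichotomization of the root→terminus path, chi-squared (Monte-Carlo p)
  tests of cell-type transitions across pseudotime compartments, per-type
  emergence quantiles ("maturation delay"), branch-point module-score
  profiles, and a transcript co-expression index for an early/late
  progenitor marker pair (top-4% positivity).
* **Synthetic cohorts** — a seeded generator producing NB counts over a
  branching maturation continuum with per-condition maturation delay,
  signature-ratio compartment mixtures, pathway activity shifts and
  per-mouse random effects, together with the ground truth needed for
  parameter-recovery testing.

## Worked example

```python
from iscaging.pipeline import load_config, run_pipeline

cfg = load_config(None, {
    "seed": 1,
    "outdir": "results/demo",
    "diffexpr": {"clusters": ["Stem"]},
})
report = run_pipeline(cfg)
print(report.table("signature_compartments")["O/Y"])
print(report.table("lgr5_stem_mean"))
print(report.table("coexpression_index")["index"])
```

This simulates the default cohort (4 conditions × 3 mice × 1,000 cells,
2,000 genes), runs QC → normalization → PCA → Louvain → annotation, DE on
the Stem cluster, module scoring, GSEA, and the trajectory analyses
(about a minute on one CPU), and prints:

```
{'compartments': [9.636, 36.8308, 21.8415, 14.7752, 13.0621, 3.8544],
 'pct_below_1': 68.3084, 'n_genes': 467}
{'O': 4.936702, 'O_met': 6.313308, 'O_rap': 5.86034, 'Y': 7.119879}
{'O': 0.324561, 'O_met': 0.177419, 'O_rap': 0.214286, 'Y': 0.08209}
```

Reading the numbers: the recovered old/young compartment vector
(9.6% of signature genes below ratio 0.5, 36.8% in 0.5–0.8, 68.3% below 1)
reflects the configured repression of the stem signature in old mice; the
Lgr5-like marker's mean normalized expression in the Stem cluster drops
from 7.12 (young) to 4.94 (old), a 31% decrease, partially restored by both
drugs; and the co-expression index of the early/late progenitor pair rises
from 0.08 (young) to 0.32 (old) — delayed maturation piles cells into the
intermediate, co-expressing state — with metformin (0.18) and rapamycin
(0.21) pulling it back toward young.  The run directory holds the full
JSON/Markdown report plus TSV artifacts (DE table, module scores,
trajectory assignments), every file stamped with the seed and config hash.

A command-line interface mirrors the stages:

```sh
iscaging simulate --seed 1 --out fixture/
iscaging run-all --seed 1 --outdir results/run
iscaging stats --test ks --file scores.tsv --values value --groups group
```

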