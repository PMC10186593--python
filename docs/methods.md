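# Methods

`iscaging` re-implements, as a tested pipeline, a single-cell analysis of
intestinal epithelial aging and its partial reversal by the geroprotectors
metformin and rapamycin.  The pipeline has two halves: an analysis library
(QC/normalization/clustering, NB mixed-model differential expression,
control-bin module scoring, signature ratio-compartment analysis, preranked
GSEA, a principal-graph trajectory with maturation-delay statistics, and a
battery of classical tests) and a ground-truthed synthetic cohort generator
that emulates the study design so every analysis can be validated by
parameter recovery.

## The synthetic cohort generator

**Design.** Four conditions — young (`Y`), old (`O`), old + metformin
(`O_met`), old + rapamycin (`O_rap`) — with 3 mice each and, by default,
1,000 cells per mouse and 2,000 genes.  Every cell carries a latent
maturation coordinate `s ~ U[0, 1]` along a stem → enterocyte continuum.
Cell types (Stem, R, R-Div, Div1, Div2, EC) occupy contiguous intervals of
`s`; the young boundaries are 0.20/0.34/0.48/0.62/0.76.  A fraction
`p_side = 0.15` of cells sit on side branches that leave the main route near
a type boundary, carry their own marker program, and have damped stage
markers.

**Aging as a maturation delay.** Each condition has a delay
`δ_c` (defaults: O 0.12, O_met 0.03, O_rap 0.05).  The delay shifts the
post-stem type boundaries right by `δ_c` (each identity emerges later) and
broadens the stage-marker transitions by a factor `1 + 2 δ_c` (intermediate,
ambiguous states become more populated).  Two gene classes deliberately
differ in how they see the delay:

* *identity programs* (25 Gaussian-bump markers per type; the Uhrf1-like /
  Ccnb1-like early/late progenitor pair) are delay-shifted;
* *positional programs* (a 200-gene monotone "crypt–villus axis" gradient,
  log-linear slopes 2–4) are **not** shifted, and the four pathway programs
  (Wnt 60, cell cycle 80, ribosome 90, OXPHOS 90 genes; smooth activity
  profiles over `s` with per-condition level multipliers) are positional as
  well.

This identity-vs-position split is what makes the delay observable: if every
program shifted together, a cell's entire expression state in an old mouse
would be indistinguishable from a younger position and no trajectory method
could, even in principle, detect a delayed emergence.  A consequence worth
knowing is that the *pipeline-estimated* delay is attenuated (roughly half
of `δ`), because the delayed identity programs also contribute to the
embedding in which cells are projected; the `emergence_delay` operation
itself recovers `δ` exactly when given latent positions, which is how it is
tested.

**Signature and marker repression.** 467 signature genes (flat in `s`) have
per-gene condition ratios `r_gc` drawn from six-compartment mixtures with
bins (0,0.5], (0.5,0.8], (0.8,1], (1,1.2], (1.2,1.5], (1.5,∞) (uniform
within a bin, top bin capped at 3.0).  The default mixture vectors are the
study conditions: O/Y = 12/38/21/14/10/4 %, O-met/Y = 5/30/37/17/7/4 %,
O-rap/Y = 4/33/36/17/7/2 % (normalized; two of the printed columns sum to
99%).  An Lgr5-like marker gene carries ratios 0.67 (O), 0.87 (O_met),
0.83 (O_rap).  A convex-pullback mode (`r_c = 1 + ε_c (r_O − 1)`) is
available as an alternative parameterization of drug reversal.

**Ratios live on the normalized scale.**  Expression ratios of this kind are
reported on depth-normalized data, so the generator defines `r_gc` as the
*normalized-scale* truth and assumes per-cell mRNA content is
condition-invariant (condition effects redistribute the transcriptome).
Concretely, the non-ratio part of each cell's rate vector is normalized to a
constant total and the ratio-carrying genes are rescaled per condition by
`N / (N + S_Y − S_c)`, which makes the expected normalized-expression ratio
of every signature gene equal its drawn `r_gc`.  Without this closure the
compositional coupling between the repressed signature and the remaining
genes biases recovered ratios by several percent.

**Counts.** Mean = (library size, log-normal with mean 5,000 and log-SD
0.3) × (per-mouse log-normal intercept, log-SD 0.15) × (per-cell rate);
counts are negative binomial with size `θ = 10` (UMI-scale overdispersion).
13 `mt-` genes hold a 5% expression share so the QC filter is exercisable.
Everything is drawn from one seeded generator; identical config + seed is
bit-identical.

**What the generator does not emulate:** batch/ambient/doublet artifacts,
UMI-level read structure, spatial coordinates, unequal per-condition
capture, and discreteness of real cluster structure (the continuum produces
boundary cells that mix adjacent stages).  Passing recovery tests therefore
demonstrates correctness of the estimators under the generator's
assumptions, not robustness to real-data artifacts — notably, because
identity is delayed, clusters at default scale are partly condition-specific
(real studies handle this with cross-sample integration, which is
deliberately out of scope here).

## Analysis choices

* **QC**: cells with detected genes < 200 or > 5000, or mitochondrial
  fraction > 20%, are removed; the printed bounds are exclusive (a 200-gene
  cell is kept).  Normalization is `log1p(1e4·count/total)`.
* **Embedding/clustering**: top variable genes by standardized dispersion
  (default all 2,000), scaled PCA (30 components, deterministic sign
  convention: the largest-magnitude loading of each component is positive),
  shared-nearest-neighbor graph (k = 15, Jaccard weights, weak edges
  pruned), Louvain via igraph with modularity resolution 2.5.  igraph's
  resolution scale is coarser than some toolkits'; 2.5 yields ~45–60
  clusters at default scale, which the marker-based annotation then maps
  onto types (winner-take-all over marker-set mean expression, ties broken
  lexicographically).
* **Cluster mean expression** (`mean_expression_by_condition`) averages
  per mouse and then per condition, on the linear (depth-normalized) scale
  by default — the convention under which a ratio of means estimates the
  expression-rate ratio; means of log-transformed values compress ratios
  toward 1 by an expression-level-dependent amount.  Log-scale averaging is
  available via `scale="log"`.
* **Module scores**: 24 equal-frequency bins of dataset-average expression,
  100 control genes per set gene drawn with replacement from the gene's bin
  excluding set genes (exclusion makes the score exactly translation-
  covariant), score = mean(set) − mean(pooled controls), mandatory seed.
* **NB mixed model**: per-gene NB likelihood, log link, offset
  log(cell total), fixed condition effects, Gaussian per-mouse intercept.
  Inner penalized Newton for (β, u); Laplace-approximated marginal over the
  intercepts; outer Nelder–Mead over (log θ, log σ) with a REML-style
  adjustment (adds half the log-determinant of the profiled fixed-effect
  covariance) that removes most of the small-sample downward bias in σ̂.
  The Wald test uses a t reference with between-mouse df when σ̂ > 1e-3 and
  cell-level df otherwise; under null simulations with 6 mice and mouse SD
  ∈ {0, 0.3} the empirical size at α = 0.05 is ≈ 0.03–0.05.  All-zero genes
  are flagged `non_estimable`; non-converged fits are flagged, never
  dropped silently.  A mouse-level pseudobulk NB regression (statsmodels)
  is the fast fallback used for genome-wide scans; BH is the default
  multiplicity correction with Bonferroni available.
* **DEG counting** uses |logFC| ≥ ln 1.5 (the ≥ convention) and adjusted
  p < 0.01.
* **Preranked GSEA**: genes ranked by DE logFC (ties by gene id), classic
  weighted running-sum statistic (weight 1; hits add |metric|ʷ normalized
  over hits, misses subtract 1/(N − n_set)), ES = signed extremum.  Null by
  gene-label permutations preserving set size; NES = ES / mean |null ES| of
  matching sign; nominal p counts |null ES| ≥ |ES| with a +1 pseudo-count;
  BH across sets.  A set covering the whole list has ES 1 by convention and
  is flagged degenerate.
* **Trajectory**: medoid per cluster (member nearest the cluster mean), MST
  over medoids (Euclidean, deterministic), cells projected onto the nearest
  point of an edge incident to their cluster's medoid, pseudotime =
  geodesic distance from the Stem medoid min-max normalized to [0, 1].
  Main/side/excluded is decided at the cluster level: clusters on the
  unique root→terminus path are main; clusters attached to it before the
  terminus are side; clusters whose route to the root passes through the
  terminus are excluded.  Pseudotime compartments default to main-path
  tertiles.  Emergence uses the 0.05 quantile of a type's main-cell
  pseudotimes (a robust operationalization of "first detection"), requiring
  ≥ 20 cells.
* **Co-expression index**: per-gene positivity above the 0.96 quantile
  within the scope; index = |co-positive| / (|pos early| + |pos late|).
* **Statistics**: two-sample KS with asymptotic p; one-way ANOVA with
  Tukey HSD (studentized range); two-response MANOVA by Pillai trace with
  the standard F approximation (mice as independent units; Wilks not
  implemented); Pearson chi-squared with Monte-Carlo p from
  margin-preserving table sampling (uniform via label shuffling),
  p = (1 + #{sim ≥ obs}) / (n_sim + 1).  Degenerate inputs (all-identical
  groups, zero within-variance, singular covariance) are flagged
  explicitly; the all-equal case reports p = 1 by convention.

## Problem sizes

Default scale is 4 × 3 × 1,000 cells × 2,000 genes; a full pipeline run
(simulate → report) takes a few minutes on one CPU with genome-wide
pseudobulk DE on the Stem cluster (the GLMM is per-gene and is used for
focused contrasts).  Recovery tests run on this scale; calibration and
power studies of the transition test use latent-only cohorts (no counts),
200 null and 50 delayed replicates.  The test suite uses a shared reduced
cohort (150 cells/mouse, 1,400 genes) for integration-level checks.

## Known limitations

* The trajectory is a deterministic medoid-MST stand-in for principal-graph
  learners; an externally computed trajectory can be supplied as
  vertex/edge/projection tables.
* Pipeline-level emergence delays are attenuated and, at default scale,
  some type × condition cells fall below the 20-cell minimum and are
  reported missing.
* The Wald/Laplace inference is approximate for very low-count genes
  (flagged via convergence status); no zero-inflation.
* The 467-gene signature is a synthetic stand-in; real signature and
  pathway gene sets can be supplied as GMT files.
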