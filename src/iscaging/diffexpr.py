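"""Negative-binomial mixed-model differential expression.

Each gene is modeled separately: cell counts are NB-distributed with a log
link, fixed condition effects, an offset of log(total counts per cell), and
a Gaussian random intercept per mouse integrated out by a Laplace
approximation (the ``glmer.nb`` model family).  The NB size parameter and
the random-intercept SD are profiled by an outer derivative-free optimizer
around an inner penalized Newton solve for the fixed effects and mouse
modes; the Wald test of the condition coefficient uses the profiled-out
covariance of the fixed effects.

A mouse-level pseudobulk NB regression is provided as a fast fallback and
cross-check estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.stats as st
from scipy.special import gammaln

log = logging.getLogger(__name__)

LOG15 = float(np.log(1.5))


@dataclass
class DEResult:
    gene: str
    contrast: str                 # "O_vs_Y" style
    logfc: float                  # natural-log scale
    se: float
    re_sd: float                  # random-intercept SD estimate
    nb_size: float                # NB size (theta) estimate
    p: float
    converged: str                # ok | non_estimable | max_iter
    n_cells: dict
    df: float = np.inf            # reference df of the Wald t statistic

    def to_row(self) -> dict:
        return {"gene": self.gene, "contrast": self.contrast,
                "logfc": self.logfc, "se": self.se, "re_sd": self.re_sd,
                "nb_size": self.nb_size, "p": self.p, "df": self.df,
                "converged": self.converged, **{f"n_{k}": v
                                                for k, v in self.n_cells.items()}}


def _nb_loglik(y, mu, theta):
    return np.sum(gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
                  + theta * np.log(theta / (theta + mu))
                  + y * np.log(mu / (theta + mu) + 1e-300))


def _penalized_newton(y, X, Z, offset, theta, sigma, z0=None, max_iter=50,
                      tol=1e-8):
    """Joint Newton for (beta, u) of the penalized NB log-likelihood.

    Returns (z, penalized_ll, A, ok) where A is the final negative Hessian.
    """
    n, p = X.shape
    m = Z.shape[1]
    J = np.hstack([X, Z])
    pen = np.zeros(p + m)
    if m:
        pen[p:] = 1.0 / max(sigma, 1e-8) ** 2
    z = np.zeros(p + m) if z0 is None else z0.copy()
    # crude intercept start keeps exp() in range
    if z0 is None:
        z[0] = np.log((y.sum() + 0.5) / np.exp(offset).sum())

    def objective(z):
        eta = offset + J @ z
        mu = np.exp(np.clip(eta, -30, 30))
        return _nb_loglik(y, mu, theta) - 0.5 * np.sum(pen * z ** 2), mu

    f, mu = objective(z)
    ok = False
    A = None
    for _ in range(max_iter):
        grad_eta = y - (y + theta) * mu / (mu + theta)
        w = (y + theta) * theta * mu / (mu + theta) ** 2
        grad = J.T @ grad_eta - pen * z
        A = J.T @ (w[:, None] * J) + np.diag(pen)
        A[np.diag_indices_from(A)] += 1e-10
        try:
            step = np.linalg.solve(A, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        t = 1.0
        for _ in range(30):
            f_new, mu_new = objective(z + t * step)
            if f_new >= f - 1e-12:
                break
            t /= 2
        z = z + t * step
        f, mu = f_new, mu_new
        if np.max(np.abs(grad)) < tol * (1 + abs(f)):
            ok = True
            break
    return z, f, A, ok


def _laplace_marginal(y, X, Z, offset, theta, sigma, z0=None, reml=False):
    """Laplace-approximated marginal log-likelihood at (theta, sigma).

    With ``reml=True`` the profiled fixed-effect information is added as a
    restricted-likelihood adjustment (reduces the small-sample downward
    bias of the variance parameters).
    """
    z, pen_ll, A, ok = _penalized_newton(y, X, Z, offset, theta, sigma, z0)
    p = X.shape[1]
    m = Z.shape[1]
    if m and sigma > 1e-8:
        eta = offset + np.hstack([X, Z]) @ z
        mu = np.exp(np.clip(eta, -30, 30))
        w = (y + theta) * theta * mu / (mu + theta) ** 2
        d = Z.T @ (w[:, None] * Z)
        corr = -0.5 * np.sum(np.log(sigma ** 2 * np.diag(d) + 1.0))
    else:
        corr = 0.0
    if reml and A is not None:
        try:
            cov_b = np.linalg.inv(A)[:p, :p]
            sign, logdet = np.linalg.slogdet(cov_b)
            if sign > 0:
                corr += 0.5 * logdet  # -0.5 log det(profiled information)
        except np.linalg.LinAlgError:
            pass
    return pen_ll + corr, z, A, ok


def fit_nb_glmm(counts_g, condition, mouse, totals, contrast=None,
                re_sd: float | None = None, gene: str = "gene") -> DEResult:
    """Fit the per-gene NB mixed model and Wald-test the condition effect.

    Parameters
    ----------
    counts_g, condition, mouse, totals : per-cell vectors.
    contrast : (test, reference) pair of condition labels; defaults to the
        two labels present (test = the non-reference), reference = "Y" when
        present else the lexicographically first label.
    re_sd : fix the random-intercept SD (0 reduces the model to a plain NB
        regression); ``None`` estimates it.
    """
    y = np.asarray(counts_g, dtype=float)
    condition = np.asarray(condition)
    mouse = np.asarray(mouse)
    totals = np.asarray(totals, dtype=float)
    levels = sorted(pd.unique(condition).tolist())
    if len(levels) < 2:
        raise ValueError("need >= 2 conditions")
    if contrast is None:
        ref = "Y" if "Y" in levels else levels[0]
        others = [l for l in levels if l != ref]
        contrast = (others[0], ref)
    test_lvl, ref_lvl = contrast
    if test_lvl not in levels or ref_lvl not in levels:
        raise ValueError(f"contrast {contrast} not present in condition labels")
    name = f"{test_lvl}_vs_{ref_lvl}"
    n_cells = {lvl: int(np.sum(condition == lvl)) for lvl in levels}
    if y.sum() == 0:
        return DEResult(gene, name, np.nan, np.nan, np.nan, np.nan, np.nan,
                        "non_estimable", n_cells)

    ordered = [ref_lvl] + [l for l in levels if l != ref_lvl]
    X = np.ones((len(y), len(ordered)))
    for j, lvl in enumerate(ordered[1:], start=1):
        X[:, j] = (condition == lvl).astype(float)
    mice = sorted(pd.unique(mouse).tolist())
    Z = (mouse[:, None] == np.array(mice)[None, :]).astype(float)
    offset = np.log(totals)
    coef_idx = ordered.index(test_lvl)

    state = {"z0": None}

    def negll(x):
        theta = np.exp(x[0])
        sigma = np.exp(x[1]) if re_sd is None else re_sd
        ll, z, _, _ = _laplace_marginal(y, X, Z, offset, theta, sigma,
                                        state["z0"], reml=(re_sd is None))
        state["z0"] = z
        return -ll

    if re_sd is not None:
        res = opt.minimize_scalar(lambda t: negll([t]), bounds=(-7, 9),
                                  method="bounded",
                                  options={"xatol": 1e-6})
        theta = float(np.exp(res.x))
        sigma = float(re_sd)
    else:
        res = opt.minimize(negll, np.array([np.log(1.0), np.log(0.3)]),
                           method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": 1e-7,
                                    "maxiter": 400})
        theta = float(np.exp(res.x[0]))
        sigma = float(np.exp(res.x[1]))
        if sigma < 1e-6:
            sigma = 0.0
    _, z, A, inner_ok = _laplace_marginal(y, X, Z, offset, theta, sigma,
                                          state["z0"])
    p_fix = X.shape[1]
    try:
        cov = np.linalg.inv(A)[:p_fix, :p_fix]
        se = float(np.sqrt(max(cov[coef_idx, coef_idx], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
    logfc = float(z[coef_idx])
    # Wald reference: with an active random intercept the experimental unit
    # is the mouse, so the t reference uses between-mouse df; a (near-)zero
    # intercept reduces the model to a cell-level GLM
    if sigma > 1e-3:
        df = float(max(len(mice) - p_fix, 1))
    else:
        df = float(max(len(y) - p_fix, 1))
    if not inner_ok or not np.isfinite(se) or se == 0:
        flag = "max_iter"
        log.warning("gene %s: mixed-model fit did not converge", gene)
        pval = np.nan
    else:
        flag = "ok"
        pval = float(2 * st.t.sf(abs(logfc) / se, df))
    return DEResult(gene, name, logfc, se, sigma, theta, pval, flag, n_cells,
                    df)


def fit_nb_pseudobulk(counts_g, condition, mouse, totals, contrast=None,
                      gene: str = "gene") -> DEResult:
    """Mouse-level pseudobulk NB regression (fast fallback estimator)."""
    import statsmodels.api as sm
    from statsmodels.discrete.discrete_model import NegativeBinomial

    df = pd.DataFrame({"y": np.asarray(counts_g, dtype=float),
                       "condition": np.asarray(condition),
                       "mouse": np.asarray(mouse),
                       "total": np.asarray(totals, dtype=float)})
    agg = df.groupby(["condition", "mouse"], observed=True).sum().reset_index()
    levels = sorted(agg["condition"].unique().tolist())
    if contrast is None:
        ref = "Y" if "Y" in levels else levels[0]
        contrast = ([l for l in levels if l != ref][0], ref)
    test_lvl, ref_lvl = contrast
    name = f"{test_lvl}_vs_{ref_lvl}"
    n_cells = {lvl: int((np.asarray(condition) == lvl).sum()) for lvl in levels}
    if agg["y"].sum() == 0:
        return DEResult(gene, name, np.nan, np.nan, np.nan, np.nan, np.nan,
                        "non_estimable", n_cells)
    ordered = [ref_lvl] + [l for l in levels if l != ref_lvl]
    X = np.ones((len(agg), len(ordered)))
    for j, lvl in enumerate(ordered[1:], start=1):
        X[:, j] = (agg["condition"] == lvl).astype(float)
    model = NegativeBinomial(agg["y"].to_numpy(), X,
                             offset=np.log(agg["total"].to_numpy()))
    try:
        fit = model.fit(disp=0, maxiter=200)
        j = ordered.index(test_lvl)
        logfc = float(fit.params[j])
        se = float(fit.bse[j])
        df = float(max(len(agg) - len(ordered), 1))
        pval = float(2 * st.t.sf(abs(logfc) / se, df)) if se > 0 else np.nan
        alpha = float(fit.params[-1])
        flag = "ok" if fit.mle_retvals.get("converged", True) else "max_iter"
        return DEResult(gene, name, logfc, se, 0.0,
                        1.0 / alpha if alpha > 0 else np.inf, pval, flag,
                        n_cells, df)
    except Exception:  # pragma: no cover - statsmodels failures are flagged
        return DEResult(gene, name, np.nan, np.nan, np.nan, np.nan, np.nan,
                        "max_iter", n_cells)


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (default) or Bonferroni adjustment; monotone in p,
    NaNs passed through."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    if method == "bonferroni":
        out[ok] = np.minimum(q * m, 1.0)
        return out
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def de_table(counts, meta, norm_totals, scope_mask, contrast,
             genes=None, method: str = "glmm", cluster: str = "",
             adjust: str = "bh") -> pd.DataFrame:
    """Run per-gene DE over a cell scope; returns one row per gene.

    ``counts`` is a CountMatrix, ``norm_totals`` per-cell total counts,
    ``scope_mask`` a boolean cell selector (e.g. one cluster restricted to
    the contrast's conditions).
    """
    fit = fit_nb_glmm if method == "glmm" else fit_nb_pseudobulk
    idx = np.flatnonzero(np.asarray(scope_mask))
    condition = meta["condition"].to_numpy()[idx]
    mouse = meta["mouse"].to_numpy()[idx]
    totals = np.asarray(norm_totals, dtype=float)[idx]
    gene_list = list(genes) if genes is not None else list(counts.gene_ids)
    rows = []
    for g in gene_list:
        gi = counts.gene_ids.get_loc(g)
        y = np.asarray(counts.counts[gi, idx].todense()).ravel()
        rows.append(fit(y, condition, mouse, totals, contrast=contrast,
                        gene=g).to_row())
    out = pd.DataFrame(rows).set_index("gene")
    out["cluster"] = cluster
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method=adjust)
    return out


def count_degs(results: pd.DataFrame, fc_threshold: float = 1.5,
               padj_threshold: float = 0.01):
    """Count genes with |logFC| >= ln(fc_threshold) and adjusted p <
    padj_threshold, per cluster and contrast; non-converged genes are
    excluded from counting and reported."""
    if results.empty:
        raise ValueError("empty DE results table")
    usable = results[results["converged"] == "ok"]
    excluded = results.index[results["converged"] != "ok"].tolist()
    hits = usable[(usable["logfc"].abs() >= np.log(fc_threshold) - 1e-12)
                  & (usable["p_adj"] < padj_threshold)]
    counts = (hits.groupby(["cluster", "contrast"], observed=True)
              .size().rename("n_degs").reset_index())
    all_groups = (usable.groupby(["cluster", "contrast"], observed=True)
                  .size().rename("n_tested").reset_index())
    out = all_groups.merge(counts, how="left").fillna({"n_degs": 0})
    out["n_degs"] = out["n_degs"].astype(int)
    return out, excluded
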