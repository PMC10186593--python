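"""The statistical tests the analyses delegate to.

Two-sample Kolmogorov-Smirnov (asymptotic p), one-way ANOVA with Tukey HSD,
two-response MANOVA (Pillai trace), and Pearson chi-squared with a
Monte-Carlo simulated p from margin-preserving table sampling.  Each test
returns a uniform :class:`~iscaging.io.TestResult` and flags degenerate
inputs explicitly instead of emitting NaNs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .io import TestResult


def ks_two_sample(a, b) -> TestResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic p.

    Ties are handled by evaluating both ECDFs on the pooled support.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = st.ks_2samp(a, b, method="asymp")
    return TestResult("ks_two_sample", float(res.statistic),
                      None, float(min(res.pvalue, 1.0)),
                      {"n_a": a.size, "n_b": b.size})


def anova_tukey(values, groups, alpha: float = 0.05):
    """One-way ANOVA F((k-1, N-k)) plus Tukey-HSD pairwise adjusted p's.

    Returns ``(TestResult, pairwise_table)``.  With zero within-group
    variance everywhere the F ratio is undefined and the result is flagged
    degenerate (p = 1 when the group means are also all equal).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    samples = [values[groups == g] for g in names]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA requires >= 2 groups with >= 2 observations each")
    k, n = len(samples), values.size
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df = (k - 1, n - k)
    if ss_within == 0:
        degenerate = True
        if ss_between == 0:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    else:
        degenerate = False
        f = (ss_between / df[0]) / (ss_within / df[1])
        p = float(st.f.sf(f, *df))
    detail = {"groups": names, "alpha": alpha, "degenerate": degenerate}
    result = TestResult("anova", float(f), df, p, detail)
    pairs = []
    if not degenerate:
        hsd = st.tukey_hsd(*samples)
        for i in range(k):
            for j in range(i + 1, k):
                pairs.append({
                    "group_a": names[i], "group_b": names[j],
                    "diff": samples[i].mean() - samples[j].mean(),
                    "p_adj": float(hsd.pvalue[i, j]),
                    "significant": bool(hsd.pvalue[i, j] < alpha),
                })
    pairwise = pd.DataFrame(pairs)
    return result, pairwise


def manova_two_response(Y, groups) -> TestResult:
    """Two-response one-way MANOVA, Pillai trace with its F approximation.

    Observational units (here: mice) are treated as independent.  Identical
    group means give Pillai ~ 0 and, in the exactly-degenerate all-equal
    case, p = 1 by convention.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("Y must be n x 2")
    names = sorted(pd.unique(groups).tolist())
    k, n, p_resp = len(names), Y.shape[0], 2
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    grand = Y.mean(axis=0)
    H = np.zeros((2, 2))
    E = np.zeros((2, 2))
    for g in names:
        yg = Y[groups == g]
        d = (yg.mean(axis=0) - grand)[:, None]
        H += len(yg) * d @ d.T
        E += (yg - yg.mean(axis=0)).T @ (yg - yg.mean(axis=0))
    if np.allclose(H, 0) and np.allclose(E, 0):
        return TestResult("manova_pillai", 0.0, None, 1.0,
                          {"degenerate": True, "groups": names})
    if np.linalg.matrix_rank(E) < p_resp:
        raise np.linalg.LinAlgError(
            "singular within-group covariance (collinear responses?)")
    eigvals = np.linalg.eigvals(np.linalg.solve(E, H)).real
    eigvals = np.clip(eigvals, 0, None)
    pillai = float(np.sum(eigvals / (1 + eigvals)))
    s = min(p_resp, k - 1)
    m = (abs(p_resp - (k - 1)) - 1) / 2
    nn = (n - k - p_resp - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (pillai / (s - pillai)) * (df2 / df1) if s > pillai else np.inf
    p = float(st.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return TestResult("manova_pillai", pillai, (df1, df2), p,
                      {"F": float(f), "groups": names, "degenerate": False})


def _sample_fixed_margin_tables(row_margins, col_margins, n_sim, rng):
    """Uniform r x c tables with both margins fixed, by shuffling a vector
    of column labels against fixed row labels (Patefield-style sampling)."""
    rows = np.repeat(np.arange(len(row_margins)), row_margins)
    cols = np.repeat(np.arange(len(col_margins)), col_margins)
    r, c = len(row_margins), len(col_margins)
    out = np.empty((n_sim, r, c), dtype=np.int64)
    for i in range(n_sim):
        perm = rng.permutation(cols)
        out[i] = np.bincount(rows * c + perm, minlength=r * c).reshape(r, c)
    return out


def chisq_mc(table, n_sim: int = 2000, seed: int = 0) -> TestResult:
    """Pearson chi-squared with a Monte-Carlo p from fixed-margin tables.

    p = (1 + #{simulated stat >= observed}) / (n_sim + 1).
    """
    table = np.asarray(table)
    if table.ndim != 2:
        raise ValueError("table must be 2-D")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must hold non-negative integers")
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise ValueError("zero row/column margin")
    total = table.sum()
    expected = np.outer(row_m, col_m) / total

    def stat(t):
        return ((t - expected) ** 2 / expected).sum(axis=(-2, -1))

    observed = float(stat(table))
    rng = np.random.default_rng(seed)
    sims = _sample_fixed_margin_tables(row_m, col_m, n_sim, rng)
    null = stat(sims)
    p = float((1 + np.sum(null >= observed - 1e-12)) / (n_sim + 1))
    return TestResult("chisq_mc", observed,
                      (table.shape[0] - 1) * (table.shape[1] - 1), p,
                      {"n_sim": n_sim, "seed": seed})
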