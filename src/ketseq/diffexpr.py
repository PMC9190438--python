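"""Voom-style precision weights and empirical-Bayes moderated F tests.

Each region x sex experiment is modeled separately on raw counts: counts
are converted to log2 counts-per-million, a lowess trend of sqrt(residual
standard deviation) against mean log-count converts the count
mean-variance relationship into per-observation inverse-variance weights,
and gene-wise weighted least-squares fits are moderated by shrinking
residual variances toward a prior estimated across genes.

The prior (d0, s0^2) is estimated by the method of moments on the log
residual variances: under the scaled-F model s^2 ~ s0^2 * F(d_res, d0),
the variance of log s^2 exceeds trigamma(d_res/2) by trigamma(d0/2), which
is inverted numerically.  Gene-level significance is the moderated F for
equality of all group means, with Benjamini-Hochberg adjustment across
genes within the experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import GROUPS, CountMatrix, compute_fpkm

__all__ = [
    "group_design",
    "voom_weights",
    "fit_moderated",
    "bh_adjust",
    "estimate_moderation",
    "run_de",
]


def group_design(groups, levels=None) -> pd.DataFrame:
    """Cell-means indicator design (one column per group)."""
    groups = pd.Series(list(groups))
    if levels is None:
        levels = [g for g in GROUPS if g in set(groups)] or sorted(set(groups))
    X = pd.DataFrame(0.0, index=range(len(groups)), columns=list(levels))
    for lv in levels:
        X.loc[(groups == lv).to_numpy(), lv] = 1.0
    if (X.sum(axis=1) != 1.0).any():
        raise ValueError("every sample must belong to exactly one group")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (empty group?)")
    return X


def _batched_wls(y: np.ndarray, w: np.ndarray, X: np.ndarray):
    """Per-gene weighted least squares.  y, w: (G, n); X: (n, p)."""
    xtwx = np.einsum("np,gn,nq->gpq", X, w, X)
    xtwy = np.einsum("np,gn,gn->gp", X, w, y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    fitted = beta @ X.T
    rss = (w * (y - fitted) ** 2).sum(axis=1)
    return beta, fitted, rss


def voom_weights(counts: CountMatrix, design: pd.DataFrame, span: float = 0.5):
    """Log2-CPM matrix and precision weights from the mean-variance trend.

    Returns ``(logcpm, weights)`` DataFrames shaped like the count matrix.
    Weights are the inverse fourth power of the lowess-predicted
    sqrt(residual sd) at each observation's fitted log-count, clipped to
    [1e-6, 1e6].
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n != counts.counts.shape[1]:
        raise ValueError("design rows must match the number of samples")
    if n <= p:
        raise ValueError("fewer samples than design columns")

    lib = counts.library_sizes.to_numpy(dtype=float)
    c = counts.counts.to_numpy(dtype=float)
    logcpm = np.log2((c + 0.5) / (lib + 1.0) * 1e6)

    beta, fitted, rss = _batched_wls(logcpm, np.ones_like(logcpm), X)
    df = n - p
    sd = np.sqrt(rss / df)
    sy = np.sqrt(sd)  # quarter-root variance, as in the voom trend
    sx = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)

    lo = lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], np.maximum(lo[:, 1], 1e-6)
    fitted_count = fitted + (np.mean(np.log2(lib + 1.0)) - np.log2(1e6))
    pred = np.interp(fitted_count, lx, ly)
    w = np.clip(pred**-4.0, 1e-6, 1e6)

    idx, cols = counts.counts.index, counts.counts.columns
    return (
        pd.DataFrame(logcpm, index=idx, columns=cols),
        pd.DataFrame(w, index=idx, columns=cols),
    )


def estimate_moderation(s2: np.ndarray, df: int):
    """Method-of-moments prior (d0, s0_sq) from gene-wise variances."""
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        return 0.0, float(np.exp(z.mean())) if z.size else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean, evar = float(e.mean()), float(e.var(ddof=1))
    gap = evar - float(special.polygamma(1, df / 2.0))
    if gap <= 0:
        return np.inf, float(np.exp(emean))
    # invert trigamma(d0/2) = gap by Newton's method
    x = 0.5 + 1.0 / gap
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / gap) / float(special.polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame,
    design: pd.DataFrame,
    reduced: pd.DataFrame = None,
    d0: float = None,
    s0_sq: float = None,
) -> pd.DataFrame:
    """Moderated F test of the full design against a reduced design.

    By default the reduced design is intercept-only, so the test is for
    equality of all group means.  Pass ``d0=0`` for unmoderated weighted
    least squares, ``d0=np.inf`` for full shrinkage to ``s0_sq``; by
    default both hyperparameters are estimated across genes.

    Returns a DataFrame indexed by gene with columns coef_<col>..., F, p,
    adj_p, df_residual, posterior_var, s2.
    """
    y = np.asarray(logcpm, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if y.shape != w.shape or y.shape[1] != n:
        raise ValueError("logcpm, weights and design are not conformable")
    df_res = n - p
    if df_res <= 0:
        raise ValueError("zero residual degrees of freedom")
    if reduced is None:
        Xr = np.ones((n, 1))
    else:
        Xr = np.asarray(reduced, dtype=float)
    q = p - Xr.shape[1]
    if q < 1:
        raise ValueError("reduced design must be nested with fewer columns")

    beta, _, rss_full = _batched_wls(y, w, X)
    _, _, rss_red = _batched_wls(y, w, Xr)
    s2 = rss_full / df_res

    if d0 is None:
        d0, s0_hat = estimate_moderation(s2, df_res)
        if s0_sq is None:
            s0_sq = s0_hat
    elif d0 > 0 and s0_sq is None:
        _, s0_sq = estimate_moderation(s2, df_res)

    if np.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        post_var = s2
        df_total = df_res
    else:
        post_var = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res

    num = (rss_red - rss_full) / q
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / post_var
    F = np.where(post_var > 0, F, np.inf)
    F = np.maximum(F, 0.0)
    if np.isinf(df_total):
        pvals = stats.chi2.sf(q * F, q)
    else:
        pvals = stats.f.sf(F, q, df_total)
    pvals = np.where(np.isfinite(F), pvals, 0.0)

    out = pd.DataFrame(index=logcpm.index)
    for j, col in enumerate(design.columns if hasattr(design, "columns") else range(p)):
        out[f"coef_{col}"] = beta[:, j]
    out["F"] = F
    out["p"] = pvals
    out["adj_p"] = bh_adjust(pvals)
    out["df_residual"] = df_res
    out["posterior_var"] = post_var
    out["s2"] = s2
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: CountMatrix,
    region: str,
    sex: str,
    span: float = 0.5,
    d0: float = None,
) -> pd.DataFrame:
    """Full per-experiment analysis: subset, voom, moderated F, FPKM means.

    Returns a DataFrame with per-group mean expression (``mean_<group>``),
    the moderated F, nominal and BH-adjusted p-values.
    """
    if counts.meta is None:
        raise ValueError("count matrix has no sample metadata")
    sel = (counts.meta["region"] == region) & (counts.meta["sex"] == sex)
    ids = list(counts.meta.loc[sel, "sample_id"])
    if not ids:
        raise ValueError(f"no samples for experiment ({region}, {sex})")
    sub = CountMatrix(
        counts=counts.counts[ids],
        gene_lengths=counts.gene_lengths,
        library_sizes=counts.library_sizes[ids],
        meta=counts.meta.loc[sel].reset_index(drop=True),
    )
    design = group_design(sub.meta["group"])
    logcpm, w = voom_weights(sub, design, span=span)
    res = fit_moderated(logcpm, w, design, d0=d0)

    expr = compute_fpkm(sub)
    means = expr.group_means(region, sex)
    out = means.add_prefix("mean_")
    for col in ["F", "p", "adj_p", "df_residual", "posterior_var"]:
        out[col] = res[col]
    out.attrs.update(res.attrs)
    out.attrs["region"], out.attrs["sex"] = region, sex
    return out
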