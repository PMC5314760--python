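"""Calling and ranking of functional DNA-methylation driver genes.

The core statistic is an empirical-Bayes moderated two-sample t: per-gene
residual variances s_g^2 (pooled, d_g degrees of freedom) are shrunk toward
a scaled-inverse-chi-square prior (d_0, s_0^2) fitted across genes by
method of moments on log s_g^2, giving the posterior variance

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

and t-statistics referred to a t distribution with d_g + d_0 degrees of
freedom. A gene is a candidate functional DNAm driver when both its
promoter methylation and its expression change significantly (BH FDR<0.05,
|Δβ|>0.1, |log2FC|>1) with *opposite* t signs: hypermethylated/
underexpressed (HyperM) or hypomethylated/overexpressed (HypoM). Candidates
are ranked by an integrative score S = (|t_meth| + |t_expr|)/2 and finally
filtered by a multivariate regression of expression on methylation and
copy-number state over all samples, so that the anti-correlation is not
explained by concomitant copy-number change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "moderated_t",
    "build_diff_stats",
    "call_dnam_de",
    "classify_and_rank",
    "multivariate_filter",
    "tissue_specific_genes",
]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_inv_chisq_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0^2) of a scaled inverse-chi-square prior to observed s^2.

    Method of moments on z = log s^2, whose mean/variance under the prior
    involve digamma/trigamma functions of the degrees of freedom; an
    infinite d0 (all variances equal) is returned when the observed spread
    of z is no larger than expected from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >=2 positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def moderated_t(values: pd.DataFrame, tumor_mask: np.ndarray,
                prior_df: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t per gene (tumor vs normal).

    Parameters
    ----------
    values : genes x samples matrix.
    tumor_mask : boolean per column; True marks the tumor group.
    prior_df : override for the prior degrees of freedom d0 (``0`` gives the
        ordinary two-sample t; ``None`` fits d0 from the data).

    Returns a DataFrame with columns t, p, df, mean_diff (tumor − normal);
    positive t means tumor > normal.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    x = values.to_numpy(dtype=float)
    t_idx, n_idx = tumor_mask, ~tumor_mask
    n1, n2 = int(t_idx.sum()), int(n_idx.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 samples in each group")
    if x.shape[0] < 2:
        raise ValueError("need >=2 genes for variance pooling")
    m1 = x[:, t_idx].mean(axis=1)
    m2 = x[:, n_idx].mean(axis=1)
    dg = n1 + n2 - 2
    ss = ((x[:, t_idx] - m1[:, None]) ** 2).sum(axis=1) + \
         ((x[:, n_idx] - m2[:, None]) ** 2).sum(axis=1)
    sg2 = ss / dg

    if prior_df is None:
        if (sg2 <= 0).all():
            warnings.warn("all residual variances are zero; ordinary t used")
            d0, s02 = 0.0, 0.0
        else:
            d0, s02 = fit_inv_chisq_prior(sg2, dg)
    else:
        d0 = float(prior_df)
        if d0 == 0:
            s02 = 0.0
        else:
            pos = sg2[sg2 > 0]
            e = np.log(pos) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
            adj = (special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
                   if np.isfinite(d0) else 0.0)
            s02 = float(np.exp(e.mean() + adj))

    if np.isinf(d0):
        post = np.full_like(sg2, s02)
        df_total = np.inf
    else:
        post = (d0 * s02 + dg * sg2) / (d0 + dg)
        df_total = dg + d0
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[(se == 0)] = 1.0
    return pd.DataFrame(
        {"t": t, "p": p, "df": df_total, "mean_diff": m1 - m2}, index=values.index)


@dataclass(frozen=True)
class DnamThresholds:
    """Significance thresholds of the functional DNAm driver call."""
    fdr_max: float = 0.05
    min_delta_beta: float = 0.1
    min_abs_log2fc: float = 1.0


def build_diff_stats(meth: pd.DataFrame, expr: pd.DataFrame,
                     tumor_mask: np.ndarray,
                     prior_df: float | None = None) -> pd.DataFrame:
    """Differential statistics per gene shared by methylation and expression.

    Restricted to genes present in both matrices; FDR (Benjamini–Hochberg)
    is computed within each data type.
    """
    genes = meth.index.intersection(expr.index)
    meth = meth.loc[genes]
    expr = expr.loc[genes, meth.columns]
    mt = moderated_t(meth, tumor_mask, prior_df=prior_df)
    et = moderated_t(expr, tumor_mask, prior_df=prior_df)
    stats_df = pd.DataFrame({
        "t_meth": mt["t"], "p_meth": mt["p"],
        "t_expr": et["t"], "p_expr": et["p"],
        "delta_beta": mt["mean_diff"], "log2fc": et["mean_diff"],
    }, index=genes)
    stats_df["fdr_meth"] = multipletests(stats_df["p_meth"], method="fdr_bh")[1]
    stats_df["fdr_expr"] = multipletests(stats_df["p_expr"], method="fdr_bh")[1]
    return stats_df


def call_dnam_de(stats_df: pd.DataFrame,
                 thresholds: DnamThresholds = DnamThresholds()) -> pd.DataFrame:
    """Keep genes significant in both data types at the stated effect sizes."""
    th = thresholds
    keep = (
        (stats_df["fdr_meth"] < th.fdr_max)
        & (stats_df["delta_beta"].abs() > th.min_delta_beta)
        & (stats_df["fdr_expr"] < th.fdr_max)
        & (stats_df["log2fc"].abs() > th.min_abs_log2fc)
    )
    return stats_df.loc[keep]


def classify_and_rank(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Split significant genes into HyperM / HypoM and rank by S.

    HyperM: methylation up, expression down; HypoM mirrored. Genes whose two
    t-statistics share a sign (no anti-correlation) are discarded. Within a
    class the integrative score S = (|t_meth| + |t_expr|)/2 sorts genes
    non-increasingly; ties break by larger |t_expr|, then by gene ID.
    """
    hyper = (stats_df["t_meth"] > 0) & (stats_df["t_expr"] < 0)
    hypo = (stats_df["t_meth"] < 0) & (stats_df["t_expr"] > 0)
    out = stats_df.loc[hyper | hypo].copy()
    out["alteration_class"] = np.where(hyper.loc[out.index], "HyperM", "HypoM")
    out["score"] = (out["t_meth"].abs() + out["t_expr"].abs()) / 2.0
    out["_abs_te"] = out["t_expr"].abs()
    out = (out.rename_axis("gene").reset_index()
              .sort_values(["alteration_class", "score", "_abs_te", "gene"],
                           ascending=[True, False, False, True],
                           kind="mergesort")
              .drop(columns="_abs_te"))
    out["rank"] = out.groupby("alteration_class").cumcount() + 1
    return out.set_index("gene")


def multivariate_filter(expr: pd.DataFrame, meth: pd.DataFrame,
                        cn_state: pd.DataFrame, genes=None) -> pd.DataFrame:
    """OLS of log2 expression on methylation and numeric CN state, per gene.

    All samples (normal and tumor) enter the regression; normals carry a
    Neutral copy-number state. Returns per-gene coefficients and p-values
    (coef_dnam, p_dnam, coef_cnv, p_cnv); genes with a constant covariate
    are dropped with a warning.
    """
    if genes is None:
        genes = expr.index.intersection(meth.index)
    samples = expr.columns
    rows = {}
    dropped = []
    for g in genes:
        if g not in meth.index or g not in expr.index:
            continue
        y = expr.loc[g, samples].to_numpy(dtype=float)
        m = meth.loc[g, samples].to_numpy(dtype=float)
        c = (cn_state.loc[g, samples].to_numpy(dtype=float)
             if g in cn_state.index else np.zeros(len(samples)))
        X = np.column_stack([np.ones_like(y), m, c])
        use = [True, np.ptp(m) > 0, np.ptp(c) > 0]
        if not use[1]:
            dropped.append(g)
            continue
        Xr = X[:, [i for i, u in enumerate(use) if u]]
        n, k = Xr.shape
        if n <= k:
            dropped.append(g)
            continue
        coef, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        resid = y - Xr @ coef
        s2 = resid @ resid / (n - k)
        cov = s2 * np.linalg.pinv(Xr.T @ Xr)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = coef / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), n - k)
        rec = {"coef_dnam": coef[1], "p_dnam": pvals[1]}
        if use[2]:
            rec["coef_cnv"], rec["p_cnv"] = coef[2], pvals[2]
        else:
            rec["coef_cnv"], rec["p_cnv"] = np.nan, np.nan
        rows[g] = rec
    if dropped:
        warnings.warn(f"{len(dropped)} genes dropped (constant covariate)")
    return pd.DataFrame.from_dict(rows, orient="index")


def filter_dnam_ranked(ranked: pd.DataFrame, multivar: pd.DataFrame,
                       p_max: float = 0.05) -> pd.DataFrame:
    """Keep ranked DNAm genes whose methylation coefficient is significantly
    negative in the multivariate model; ranks are recomputed per class."""
    if multivar.empty:
        return ranked.iloc[0:0]
    ok = multivar.index[(multivar["coef_dnam"] < 0) & (multivar["p_dnam"] < p_max)]
    kept = ranked.loc[ranked.index.intersection(ok)]
    kept = kept.sort_values(["alteration_class", "rank"], kind="mergesort").copy()
    kept["rank"] = kept.groupby("alteration_class").cumcount() + 1
    return kept


def tissue_specific_genes(meth: pd.DataFrame, expr: pd.DataFrame,
                          this_tissue_mask: np.ndarray,
                          fdr_max: float = 0.05,
                          min_delta_beta: float = 0.3,
                          min_abs_log2fc: float = 2.0) -> pd.DataFrame:
    """Epigenetically regulated tissue-specific genes (normals only).

    Compares one tissue's normal samples against pooled normals of the other
    tissues with the same machinery as the cancer calls but stricter effect
    sizes (|Δβ| > 0.3, |log2FC| > 2). Sign convention: positive t means this
    tissue > others, so HyperM genes are hypermethylated in this tissue.
    """
    stats_df = build_diff_stats(meth, expr, np.asarray(this_tissue_mask, bool))
    sig = call_dnam_de(stats_df, DnamThresholds(fdr_max, min_delta_beta, min_abs_log2fc))
    return classify_and_rank(sig)
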