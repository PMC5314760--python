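"""Preprocessing of methylation beta matrices and expression matrices.

Produces the two clean gene-level inputs of the driver analyses:

* a gene-level promoter methylation matrix (beta fractions in [0, 1]),
  built from probe-level values by region priority
  TSS200 > first exon > TSS1500, with gene-body probes excluded;
* a normalized log2 expression matrix (zero substitution by the dataset
  minimum positive value, log2 transform, between-sample quantile
  normalization).

Probe-level NA handling follows the standard 450k workflow: probes missing
in more than ``max_na_fraction`` of samples are dropped, the remainder are
k-nearest-neighbour imputed over probes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

REGION_PRIORITY = ("TSS200", "FirstExon", "TSS1500")
BODY_REGION = "Body"
VALID_REGIONS = REGION_PRIORITY + (BODY_REGION,)


def clean_beta(beta: pd.DataFrame, max_na_fraction: float = 0.3, k: int = 5,
               axis: str = "probes") -> pd.DataFrame:
    """Filter high-NA probes and impute the remaining NAs by knn.

    Parameters
    ----------
    beta : probes x samples matrix of beta values in [0, 1] (NaN allowed).
    max_na_fraction : probes with a strictly larger NA fraction are removed.
    k : number of nearest neighbour probes used for imputation.
    axis : "probes" (default) computes neighbours among probe rows;
        "samples" transposes first (switchable interpretation).
    """
    if not 0 <= max_na_fraction < 1:
        raise ValueError("max_na_fraction must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if axis == "samples":
        return clean_beta(beta.T, max_na_fraction, k, axis="probes").T
    if axis != "probes":
        raise ValueError("axis must be 'probes' or 'samples'")

    na_frac = beta.isna().mean(axis=1)
    kept = beta.loc[na_frac <= max_na_fraction]
    if not kept.isna().any().any():
        return kept.copy()

    x = kept.to_numpy(dtype=float)
    out = x.copy()
    missing_rows = np.flatnonzero(np.isnan(x).any(axis=1))
    isnan = np.isnan(x)
    for i in missing_rows:
        shared = ~isnan & ~isnan[i]          # candidate x shared-sample mask
        diff = x - x[i]
        diff[~shared] = 0.0
        counts = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.where(counts > 0, (diff ** 2).sum(axis=1) / counts, np.inf))
        dist[i] = np.inf
        for j in np.flatnonzero(isnan[i]):
            donors = np.flatnonzero(~isnan[:, j] & np.isfinite(dist))
            if donors.size == 0:
                out[i, j] = np.nanmean(x[:, j])
                warnings.warn("no complete neighbour probes; column mean used")
                continue
            if donors.size < k:
                warnings.warn(
                    f"fewer than k={k} complete neighbour probes; using {donors.size}")
            order = donors[np.argsort(dist[donors], kind="stable")][:k]
            out[i, j] = x[order, j].mean()
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean of the per-column sorted values.

    Ties receive the mean of the quantile targets their positions span.
    """
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        v = x[:, j]
        order = np.argsort(v, kind="mergesort")
        sv = v[order]
        col_target = target.copy()
        # average the targets over each run of tied values
        start = 0
        while start < n:
            stop = start + 1
            while stop < n and sv[stop] == sv[start]:
                stop += 1
            if stop - start > 1:
                col_target[start:stop] = col_target[start:stop].mean()
            start = stop
        out[order, j] = col_target
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_expression(raw: pd.DataFrame, already_log2: bool = False) -> pd.DataFrame:
    """Zero-substitute, log2-transform and quantile-normalize expression.

    Zeros are replaced by the minimum positive value of the whole dataset
    before the log2 transform; columns are then quantile-normalized to a
    common distribution. With ``already_log2`` only the quantile step runs.
    """
    if already_log2:
        return quantile_normalize(raw)
    x = raw.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression counts must be non-negative")
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("all-zero expression matrix cannot be normalized")
    x = np.where(x == 0, positive.min(), x)
    logged = pd.DataFrame(np.log2(x), index=raw.index, columns=raw.columns)
    return quantile_normalize(logged)


def gene_level_methylation(beta: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe betas to one promoter value per gene.

    Per gene the mean of TSS200 probes is used; if none map there, the mean
    of first-exon probes; failing that, the mean of TSS1500 probes. Genes
    with only gene-body probes are absent from the output — body probes
    never contribute.
    """
    if beta.isna().any().any():
        raise ValueError("beta matrix must be imputed before gene-level assignment")
    bad = set(annot["region"]) - set(VALID_REGIONS)
    if bad:
        raise ValueError(f"unknown probe regions: {sorted(bad)}")
    annot = annot[annot["probe_id"].isin(beta.index)]
    rows = {}
    for gene, sub in annot.groupby("gene", sort=True):
        for region in REGION_PRIORITY:
            probes = sub.loc[sub["region"] == region, "probe_id"]
            if len(probes):
                rows[gene] = beta.loc[probes].mean(axis=0)
                break
    if not rows:
        return pd.DataFrame(columns=beta.columns)
    return pd.DataFrame.from_dict(rows, orient="index")[beta.columns]
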