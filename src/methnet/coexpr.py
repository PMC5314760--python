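"""Cross-cancer deregulation categories and epigenetic-enzyme co-expression.

Each gene in each cancer type falls into one of five deregulation
categories: HyperM_F (significant promoter hypermethylation with
significant underexpression), HyperM_NF (hypermethylation only), HypoM_F /
HypoM_NF mirrored, or NC (no significant methylation change). Cross-cancer
consistency of the category pattern is tested by permutation: the observed
statistic is the mean over cancer-type pairs of the fraction of genes with
identical categories, and the null shuffles gene labels independently
within each cancer type.

Tumor-only Pearson correlation of target genes with designated epigenetic
enzymes (DNMT1/EZH2 by default) yields a per-gene consistency label:
"positive" when r > 0 with p < 0.05 in at least half of the cancer types
with data and no cancer type significantly contradicts; "negative"
mirrored; otherwise "none".
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy import stats

from .dnam_drivers import DnamThresholds

CATEGORIES = ("HyperM_F", "HyperM_NF", "HypoM_F", "HypoM_NF", "NC")


def categorize_gene(row: pd.Series, th: DnamThresholds) -> str:
    meth_sig = (row["fdr_meth"] < th.fdr_max
                and abs(row["delta_beta"]) > th.min_delta_beta)
    expr_sig = (row["fdr_expr"] < th.fdr_max
                and abs(row["log2fc"]) > th.min_abs_log2fc)
    if not meth_sig:
        return "NC"
    if row["delta_beta"] > 0:
        return "HyperM_F" if (expr_sig and row["log2fc"] < 0) else "HyperM_NF"
    return "HypoM_F" if (expr_sig and row["log2fc"] > 0) else "HypoM_NF"


def categorize_deregulation(stats_by_type: dict[str, pd.DataFrame],
                            thresholds: DnamThresholds = DnamThresholds(),
                            genes=None) -> pd.DataFrame:
    """genes x cancer-types matrix of deregulation categories.

    Genes unmeasured in a cancer type get NaN there and are excluded from
    consistency pairs involving that type.
    """
    if genes is None:
        genes = sorted(set().union(*(df.index for df in stats_by_type.values())))
    out = pd.DataFrame(index=pd.Index(genes, name="gene"),
                       columns=list(stats_by_type), dtype=object)
    for ct, df in stats_by_type.items():
        present = df.index.intersection(out.index)
        out.loc[present, ct] = df.loc[present].apply(
            categorize_gene, axis=1, th=thresholds)
    return out


def _pairwise_agreement(cats: pd.DataFrame) -> float:
    types = cats.columns
    fracs = []
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            both = cats[[a, b]].dropna()
            if len(both):
                fracs.append((both[a] == both[b]).mean())
    return float(np.mean(fracs)) if fracs else np.nan


def consistency_empirical_p(categories: pd.DataFrame, n_perm: int = 1000,
                            seed: int = 0) -> tuple[float, float, bool]:
    """Permutation p for cross-cancer category-pattern consistency.

    Returns (p, observed statistic, at_floor); ``at_floor`` marks the
    1/(n_perm+1) resolution limit, reported as "<=" downstream.
    """
    if categories.shape[1] < 2 or categories.shape[0] < 2:
        raise ValueError("need >=2 cancer types and >=2 genes")
    observed = _pairwise_agreement(categories)
    count = 0
    vals = categories.to_numpy(dtype=object)
    # one RNG stream per cancer type, keyed by its label: the p-value is
    # invariant to the order in which cancer types are supplied
    rngs = [np.random.default_rng(np.random.SeedSequence(
        [seed, zlib.crc32(str(c).encode())])) for c in categories.columns]
    for _ in range(n_perm):
        perm = np.column_stack([
            vals[rngs[j].permutation(vals.shape[0]), j]
            for j in range(vals.shape[1])])
        if _pairwise_agreement(pd.DataFrame(perm, columns=categories.columns)) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return p, observed, count == 0


def enzyme_correlation(expr_by_type: dict[str, pd.DataFrame], targets,
                       enzymes=("DNMT1", "EZH2"), p_max: float = 0.05,
                       min_tumors: int = 10) -> pd.DataFrame:
    """Tumor-only Pearson correlation of targets with enzyme genes.

    ``expr_by_type`` maps cancer-type -> genes x *tumor* samples log2
    expression. Returns one row per (target, enzyme) with per-type r and p
    and the cross-cancer consistency label.
    """
    rows = []
    for target in targets:
        for enzyme in enzymes:
            r_by_type, p_by_type = {}, {}
            for ct, expr in expr_by_type.items():
                if expr.shape[1] < min_tumors:
                    raise ValueError(f"{ct}: fewer than {min_tumors} tumor samples")
                if target not in expr.index or enzyme not in expr.index:
                    continue
                x = expr.loc[target].to_numpy(dtype=float)
                y = expr.loc[enzyme].to_numpy(dtype=float)
                if np.std(x) == 0 or np.std(y) == 0:
                    continue   # r undefined, excluded from the label rule
                r, p = stats.pearsonr(x, y)
                r_by_type[ct], p_by_type[ct] = float(r), float(p)
            label = _consistency_label(r_by_type, p_by_type, p_max)
            row = {"target": target, "enzyme": enzyme, "label": label}
            row.update({f"r_{ct}": r_by_type.get(ct) for ct in expr_by_type})
            row.update({f"p_{ct}": p_by_type.get(ct) for ct in expr_by_type})
            rows.append(row)
    return pd.DataFrame(rows)


def _consistency_label(r_by_type: dict[str, float], p_by_type: dict[str, float],
                       p_max: float) -> str:
    n = len(r_by_type)
    if n == 0:
        return "none"
    pos_sig = sum(1 for ct in r_by_type
                  if r_by_type[ct] > 0 and p_by_type[ct] < p_max)
    neg_sig = sum(1 for ct in r_by_type
                  if r_by_type[ct] < 0 and p_by_type[ct] < p_max)
    if pos_sig >= n / 2 and neg_sig == 0:
        return "positive"
    if neg_sig >= n / 2 and pos_sig == 0:
        return "negative"
    return "none"
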