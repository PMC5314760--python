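"""Signaling-domain enrichment, pathway-level tests and meta-analysis.

Alteration-class gene lists are tested for over- or under-representation of
the combined extracellular+membrane-receptor (EC+MR) domain against the
annotated-network background with one-tailed Fisher's exact tests; DNAm
classes test for EC+MR excess (odds ratio > 1), SCNA classes for EC+MR
depletion (odds ratio < 1). Pathway-level tests compare the EC/IC split of
functionally DNAm-altered versus SCNA-altered pathway members, and p-values
are combined across cancer types with Fisher's method
(X = −2·Σ ln p ~ chi-square with 2k df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EC_MR = ("EC", "MR")

# Fisher-test direction per alteration class (EC+MR odds ratio)
CLASS_DIRECTIONS = {
    "HyperM": "greater",
    "HypoM": "greater",
    "Amplification": "less",
    "Deletion": "less",
    "Mutation": "greater",
}


def fisher_one_tailed(table, direction: str = "greater") -> tuple[float, float]:
    """One-tailed Fisher's exact test on a 2x2 table.

    Returns (odds ratio, p). The odds ratio is the sample ratio ad/bc; 0/0
    is NaN (undefined), x/0 infinity. A degenerate margin forces p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if a * d == 0 and b * c == 0:
        odds = np.nan
    elif b * c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)
    if min(a + b, c + d, a + c, b + d) == 0:
        return odds, 1.0
    p = float(stats.fisher_exact(t, alternative=direction)[1])
    return odds, p


@dataclass
class EnrichmentResult:
    """EC+MR enrichment of one alteration-class list against the background."""
    alteration_class: str
    list_size: int
    observed: int            # list genes in EC+MR
    expected: float          # list size x background EC+MR fraction
    odds_ratio: float
    p: float
    direction: str


def _split_ec_mr(genes, coarse: dict[str, str]) -> tuple[int, int]:
    ecmr = sum(1 for g in genes if coarse.get(g) in EC_MR)
    ic = sum(1 for g in genes if coarse.get(g) == "IC")
    return ecmr, ic


def domain_enrichment(genes, coarse: dict[str, str], background,
                      alteration_class: str = "HyperM",
                      direction: str | None = None) -> EnrichmentResult | None:
    """EC+MR vs IC Fisher test of a gene list against a background universe.

    ``background`` is the annotated gene universe (e.g. all network genes
    with a domain label); the tested list is intersected with it. Returns
    None for an empty (annotated) list.
    """
    direction = direction or CLASS_DIRECTIONS.get(alteration_class, "greater")
    bg = [g for g in background if coarse.get(g) in ("EC", "MR", "IC")]
    in_list = [g for g in genes if g in set(bg)]
    if not in_list:
        return None
    rest = set(bg) - set(in_list)
    a, b = _split_ec_mr(in_list, coarse)
    c, d = _split_ec_mr(rest, coarse)
    odds, p = fisher_one_tailed([[a, b], [c, d]], direction)
    bg_frac = (a + c) / len(bg)
    return EnrichmentResult(alteration_class, len(in_list), a,
                            len(in_list) * bg_frac, odds, p, direction)


def equalize_lists(lists: dict[str, list[str]]) -> dict[str, list[str]]:
    """Truncate every class list to the minimum list length across classes."""
    n = min(len(v) for v in lists.values())
    return {k: list(v)[:n] for k, v in lists.items()}


def domain_enrichment_table(lists: dict[str, list[str]], coarse: dict[str, str],
                            background, mode: str = "all-significant") -> pd.DataFrame:
    """Per-class EC+MR enrichment table ("all-significant" or "equalized")."""
    if mode == "equalized":
        lists = equalize_lists(lists)
    elif mode != "all-significant":
        raise ValueError("mode must be 'all-significant' or 'equalized'")
    rows = []
    for cls, genes in lists.items():
        res = domain_enrichment(genes, coarse, background, cls)
        if res is None:
            warnings.warn(f"{cls}: empty annotated list, no enrichment result")
            continue
        rows.append(vars(res))
    return pd.DataFrame(rows)


def pathway_domain_differential(pathway_genes, dnam_altered, scna_altered,
                                coarse: dict[str, str],
                                return_table: bool = False):
    """One-tailed p that DNAm alterations in a pathway favor the EC domain.

    The 2x2 table has rows {DNAm-altered, SCNA-altered} and columns
    {EC, IC}, restricted to pathway members with an EC or IC coarse label
    (MR members are outside the 2-domain assignment). A pathway with no
    altered genes yields p = 1 by convention.
    """
    members = [g for g in pathway_genes if coarse.get(g) in ("EC", "IC")]
    dn = [g for g in members if g in set(dnam_altered)]
    sc = [g for g in members if g in set(scna_altered)]
    a = sum(1 for g in dn if coarse[g] == "EC")
    b = len(dn) - a
    c = sum(1 for g in sc if coarse[g] == "EC")
    d = len(sc) - c
    table = np.array([[a, b], [c, d]])
    if not dn and not sc:
        warnings.warn("pathway with no altered genes: p = 1 by convention")
        p = 1.0
    else:
        _, p = fisher_one_tailed(table, "greater")
    return (p, table) if return_table else p


def pathway_dnam_ec_enrichment(pathway_genes, dnam_altered,
                               coarse: dict[str, str]) -> float:
    """One-tailed p that DNAm-altered pathway members favor EC over the
    unaltered members (rows {altered, not-altered}, columns {EC, IC})."""
    members = [g for g in pathway_genes if coarse.get(g) in ("EC", "IC")]
    altered = set(dnam_altered)
    dn = [g for g in members if g in altered]
    rest = [g for g in members if g not in altered]
    if not dn:
        return 1.0
    a = sum(1 for g in dn if coarse[g] == "EC")
    c = sum(1 for g in rest if coarse[g] == "EC")
    _, p = fisher_one_tailed([[a, len(dn) - a], [c, len(rest) - c]], "greater")
    return p


def fisher_combined(p_values) -> float:
    """Fisher's combined probability: X = −2 Σ ln p ~ chi2(2k)."""
    ps = [p for p in p_values if p is not None and not np.isnan(p)]
    if not ps:
        return np.nan
    ps = np.asarray(ps, dtype=float)
    if (ps <= 0).any():
        warnings.warn("p = 0 clamped to smallest positive float")
        ps = np.clip(ps, np.finfo(float).tiny, 1.0)
    if (ps > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    x = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(x, 2 * len(ps)))


def pathway_meta_table(pathways: dict[str, list[str]],
                       per_type_altered: dict[str, tuple[set, set]],
                       coarse: dict[str, str],
                       adjust: bool = True) -> pd.DataFrame:
    """Pathway x cancer-type p-value table with Fisher-combined meta p.

    ``per_type_altered`` maps cancer-type label -> (DNAm-altered genes,
    SCNA-altered genes). BH-adjusted meta p-values are appended as a
    labeled extension column when ``adjust``.
    """
    types = list(per_type_altered)
    rows = {}
    for name, genes in pathways.items():
        ps = {}
        for ct in types:
            dn, sc = per_type_altered[ct]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ps[ct] = pathway_domain_differential(genes, dn, sc, coarse)
        ps["meta_p"] = fisher_combined([ps[ct] for ct in types])
        rows[name] = ps
    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out.sort_values("meta_p", kind="mergesort")
    if adjust:
        out["meta_p_bh_extension"] = multipletests(
            out["meta_p"].fillna(1.0), method="fdr_bh")[1]
    return out


def cumulative_domain_table(pathways: dict[str, list[str]],
                            per_type_altered: dict[str, tuple[set, set]],
                            coarse: dict[str, str]) -> pd.DataFrame:
    """Aggregate per-type 2x2 tables by summation before testing
    (cumulative-count barplot mode)."""
    rows = []
    for name, genes in pathways.items():
        total = np.zeros((2, 2), dtype=np.int64)
        for dn, sc in per_type_altered.values():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, table = pathway_domain_differential(
                    genes, dn, sc, coarse, return_table=True)
            total += table
        _, p = fisher_one_tailed(total, "greater")
        rows.append({"pathway": name,
                     "dnam_ec": total[0, 0], "dnam_ic": total[0, 1],
                     "scna_ec": total[1, 0], "scna_ic": total[1, 1],
                     "p": p})
    return pd.DataFrame(rows).set_index("pathway")


def overlap_test(list_a, list_b, universe) -> float:
    """Hypergeometric over-representation p of the overlap of two gene lists."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(list_a) & universe
    b = set(list_b) & universe
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
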