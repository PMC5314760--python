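"""Signaling-domain-annotated protein interaction network and topology tests.

Genes are assigned to coarse signaling domains — extracellular (EC),
membrane receptor (MR), intracellular (IC) — by keyword matching against
their cellular-localization terms, and to fine domains by receptor contact:
an EC gene adjacent to an MR is a secreted factor (SF), otherwise a growth
modulator (GM); an IC gene adjacent to an MR is an intracellular receptor
substrate (ICRS), otherwise a non-receptor substrate (ICNRS).

The network itself is pruned to the signaling hierarchy: only EC-EC, EC-MR,
MR-IC and IC-IC edges are retained (MR-MR and EC-IC edges are removed) and
the largest connected component is kept. Topology comparisons between
alteration classes use one-tailed Mann-Whitney rank-sum tests on node
degrees and on within-class pairwise shortest-path lengths.
"""

from __future__ import annotations

import itertools
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

ALLOWED_COARSE_PAIRS = frozenset({
    frozenset({"EC"}), frozenset({"EC", "MR"}),
    frozenset({"MR", "IC"}), frozenset({"IC"}),
})

# localization keyword lists defining the three coarse domains
IC_KEYWORDS = [
    "Nucleus", "Cytoplasm", "Ribosome", "Nucleolus", "Mitochondri",
    "Endoplasmic reticulum", "Golgi", "Lysosome", "Cytosol", "Cytoskeleton",
    "Nuclear", "Kinetochore", "Chromosome", "Endosome", "Intracellular",
    "Nucleoplasm", "Perinuclear", "Centrosome", "Peroxisome", "Microtubule",
    "Microsome", "endosome", "Centriole", "Sarcoplasm", "Secretory granule",
    "Endocytic vesicle", "cytoskeleton", "Peroxisomal membrane", "Acrosome",
    "Zymogen granule",
]
MR_KEYWORDS = [
    "Plasma membrane", "Integral to membrane", "Cell surface",
    "Integral to plasma membrane", "Cell projection", "Basolateral membrane",
    "Axoneme", "Apical membrane",
]
EC_KEYWORDS = [
    "Extracellular", "Cell junction", "Synapse", "Dendrite", "Secreted",
    "Synaptic vesicle",
]

DEFAULT_KEYWORDS = {"IC": IC_KEYWORDS, "MR": MR_KEYWORDS, "EC": EC_KEYWORDS}


def coarse_domains(localization: dict[str, set[str]],
                   keywords: dict[str, list[str]] | None = None) -> dict[str, str]:
    """Assign every annotated gene one coarse domain in {EC, MR, IC}.

    Keyword matching is case-insensitive substring containment. Multi-domain
    hits resolve by precedence: any EC hit wins (a gene annotated both
    extracellular and transmembrane is EC); MR with IC resolves to IC; genes
    matching no keyword are unannotated and excluded from domain analyses.
    """
    keywords = keywords or DEFAULT_KEYWORDS
    lowered = {dom: [k.lower() for k in kws] for dom, kws in keywords.items()}
    out: dict[str, str] = {}
    for gene, terms in localization.items():
        tl = [t.lower() for t in terms]
        hits = {dom for dom, kws in lowered.items()
                if any(k in t for k in kws for t in tl)}
        if not hits:
            continue
        if "EC" in hits:
            out[gene] = "EC"
        elif hits == {"MR", "IC"}:
            out[gene] = "IC"
        elif hits == {"MR"}:
            out[gene] = "MR"
        else:
            out[gene] = "IC"
    return out


def fine_domains(coarse: dict[str, str], graph: nx.Graph) -> dict[str, str]:
    """Refine EC/IC genes by membrane-receptor contact (SF/GM, ICRS/ICNRS)."""
    out: dict[str, str] = {}
    for gene, dom in coarse.items():
        if dom == "MR":
            out[gene] = "MR"
            continue
        has_mr = gene in graph and any(
            coarse.get(nb) == "MR" for nb in graph.neighbors(gene))
        if dom == "EC":
            out[gene] = "SF" if has_mr else "GM"
        else:
            out[gene] = "ICRS" if has_mr else "ICNRS"
    return out


def edge_allowed(dom_a: str | None, dom_b: str | None) -> bool:
    if dom_a is None or dom_b is None:
        return False
    return frozenset({dom_a, dom_b}) in ALLOWED_COARSE_PAIRS


def prune_edges(graph: nx.Graph, coarse: dict[str, str]) -> nx.Graph:
    """Remove edges whose endpoint coarse pair is outside the allowed set."""
    pruned = graph.copy()
    drop = [(a, b) for a, b in pruned.edges
            if not edge_allowed(coarse.get(a), coarse.get(b))]
    pruned.remove_edges_from(drop)
    return pruned


def largest_component(graph: nx.Graph) -> nx.Graph:
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph: no component to extract")
    nodes = max(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)[0]))
    return graph.subgraph(nodes).copy()


def sparsity(n_nodes: int, n_edges: int) -> float:
    """Fraction of realized edges among all possible: 2E / (N(N-1))."""
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def build_pruned_pin(edges, coarse: dict[str, str]) -> nx.Graph:
    """Simple graph -> largest component -> hierarchy pruning -> largest component.

    Self-loops and duplicate edges are dropped. Node attributes carry the
    coarse and (receptor-contact-derived) fine domain labels.
    """
    g = nx.Graph()
    g.add_edges_from((a, b) for a, b in edges if a != b)
    if g.number_of_nodes() == 0:
        raise ValueError("edge list produced an empty graph")
    g = largest_component(g)
    g = prune_edges(g, coarse)
    if g.number_of_edges() == 0:
        raise ValueError("no hierarchy-consistent edges remain after pruning")
    g = largest_component(g)
    fine = fine_domains({n: coarse[n] for n in g.nodes if n in coarse}, g)
    nx.set_node_attributes(g, {n: coarse.get(n) for n in g.nodes}, "coarse")
    nx.set_node_attributes(g, {n: fine.get(n) for n in g.nodes}, "fine")
    return g


def network_stats(graph: nx.Graph) -> dict:
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    return {"nodes": n, "edges": e, "sparsity": sparsity(n, e)}


# ---------------------------------------------------------------------------
# rank-sum machinery

_EXACT_LIMIT = 20000


def rank_sum_p(x, y, alternative: str = "less") -> float:
    """One-tailed rank-sum p-value that ``x`` is stochastically smaller
    ("less") or larger ("greater") than ``y``.

    Small samples are tested by exact enumeration of all group relabelings
    of the pooled values (correct under ties); larger samples use the
    tie-corrected normal approximation of the Mann-Whitney test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return math.nan
    if math.comb(x.size + y.size, x.size) <= _EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[: x.size].sum()
        count = 0
        total = 0
        for idx in itertools.combinations(range(pooled.size), x.size):
            s = ranks[list(idx)].sum()
            if alternative == "less":
                count += s <= obs + 1e-9
            else:
                count += s >= obs - 1e-9
            total += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def map_to_network(genes, graph: nx.Graph) -> tuple[list[str], int]:
    mapped = [g for g in genes if g in graph]
    return mapped, len(genes) - len(mapped)


def degree_comparison(lists: dict[str, list[str]], graph: nx.Graph,
                      top_k: int = 100, min_mapped: int = 5) -> pd.DataFrame:
    """Pairwise one-tailed degree comparisons among alteration classes.

    Entry (row, col) is the p-value that the column class has *smaller*
    degrees than the row class; classes with fewer than ``min_mapped``
    network-mapped genes yield missing p-values.
    """
    degs = {}
    for cls, genes in lists.items():
        mapped, n_lost = map_to_network(list(genes)[:top_k], graph)
        if n_lost:
            warnings.warn(f"{cls}: {n_lost} genes not in network")
        degs[cls] = np.array([graph.degree[g] for g in mapped], dtype=float)
    classes = list(lists)
    table = pd.DataFrame(index=classes, columns=classes, dtype=float)
    for row in classes:
        for col in classes:
            if row == col:
                continue
            if len(degs[row]) < min_mapped or len(degs[col]) < min_mapped:
                warnings.warn(f"<{min_mapped} mapped genes for {row} vs {col}")
                continue
            table.loc[row, col] = rank_sum_p(degs[col], degs[row], "less")
    return table


def pooled_degree_comparison(dnam_genes, cnv_genes, graph: nx.Graph) -> float:
    """One-tailed p that pooled DNAm genes have smaller degree than CNV genes."""
    dn, _ = map_to_network(dnam_genes, graph)
    cn, _ = map_to_network(cnv_genes, graph)
    dn_deg = [graph.degree[g] for g in dn]
    cn_deg = [graph.degree[g] for g in cn]
    return rank_sum_p(dn_deg, cn_deg, "less")


def pairwise_shortest_paths(genes, graph: nx.Graph) -> np.ndarray:
    """Within-set pairwise shortest-path lengths (unweighted BFS)."""
    genes = [g for g in genes if g in graph]
    dists = []
    for i, g in enumerate(genes):
        lengths = nx.single_source_shortest_path_length(graph, g)
        for h in genes[i + 1:]:
            if h in lengths:
                dists.append(lengths[h])
    return np.asarray(dists, dtype=float)


# orientation of the one-tailed shortest-path tests: (A, B) tests whether
# class A has *longer* within-class distances than class B
SP_ALTERNATIVES = [
    ("HyperM", "HypoM"), ("HyperM", "Amplification"), ("HyperM", "Deletion"),
    ("HyperM", "Mutation"),
    ("HypoM", "Amplification"), ("HypoM", "Deletion"), ("HypoM", "Mutation"),
    ("Mutation", "Amplification"), ("Mutation", "Deletion"),
    ("Amplification", "Deletion"),
]


def shortest_path_comparison(lists: dict[str, list[str]], graph: nx.Graph,
                             top_k: int = 100,
                             pairs=None) -> pd.DataFrame:
    """One-tailed rank-sum comparisons of within-class shortest-path lengths.

    Each tested pair (A, B) asks whether A's pairwise distances are longer
    than B's; default pairs follow the alteration-class hierarchy (HyperM
    longer than all, HypoM longer than SCNA/mutation classes, Mutation
    longer than SCNA classes, Amplification longer than Deletion).
    """
    sp = {cls: pairwise_shortest_paths(list(genes)[:top_k], graph)
          for cls, genes in lists.items()}
    rows = []
    for a, b in (pairs if pairs is not None else SP_ALTERNATIVES):
        if a not in sp or b not in sp:
            continue
        if sp[a].size == 0 or sp[b].size == 0:
            rows.append({"longer": a, "shorter": b, "p": np.nan,
                         "mean_a": np.nan, "mean_b": np.nan})
            continue
        rows.append({
            "longer": a, "shorter": b,
            "p": rank_sum_p(sp[a], sp[b], "greater"),
            "mean_a": sp[a].mean(), "mean_b": sp[b].mean(),
        })
    return pd.DataFrame(rows)
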