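"""End-to-end orchestration: per-cancer-type runs and pan-cancer meta-analysis.

A run proceeds through the stages in order — preprocessing, functional DNAm
driver calling, SCNA/mutation ranking, network topology comparison and
signaling-domain enrichment — and either consumes files on disk or a
synthetic cohort generated in-process. Every written table carries a
provenance header (package version, config hash, seed) and a fixed seed
reproduces the whole bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__, io as mio
from . import coexpr as cx
from . import dnam_drivers as dd
from . import enrichment as en
from . import network as netmod
from . import preprocess as pp
from . import scna_mut as sm
from . import synth

log = logging.getLogger("methnet")

ALTERATION_CLASSES = ("HyperM", "HypoM", "Amplification", "Deletion", "Mutation")


@dataclass
class RunConfig:
    """All thresholds of one pipeline run (defaults are the analysis defaults).

    Either ``synthetic`` holds a generator configuration, or ``inputs`` maps
    the expected keys (beta, probes, expression, samples, segments,
    mutations, gene_coords, edges, localization, gmt) to file paths.
    """
    synthetic: synth.SyntheticConfig | None = None
    inputs: dict | None = None
    fdr_max: float = 0.05
    min_delta_beta: float = 0.1
    min_abs_log2fc: float = 1.0
    tissue_delta_beta: float = 0.3
    tissue_log2fc: float = 2.0
    top_k: int = 100
    max_na_fraction: float = 0.3
    knn_k: int = 5
    multivar_p: float = 0.05
    expression_scale: str = "log2"   # "log2" (already transformed) or "counts"
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = synth.SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    def provenance(self) -> list[str]:
        analytic = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return [f"methnet {__version__}",
                f"config_hash={mio.config_hash(analytic)}",
                f"seed={self.seed}"]


@dataclass
class CancerBundle:
    """Everything one per-cancer-type run produces."""
    cancer_type: str
    config: RunConfig
    net: nx.Graph
    coarse: dict
    pathways: dict
    diff_stats: pd.DataFrame
    ranked_dnam: pd.DataFrame
    call_matrix: pd.DataFrame
    amp_ranked: pd.DataFrame
    del_ranked: pd.DataFrame
    mut_ranked: pd.DataFrame
    top_lists: dict
    degree_table: pd.DataFrame
    pooled_degree_p: float
    sp_table: pd.DataFrame
    enrichment_all: pd.DataFrame
    enrichment_equalized: pd.DataFrame
    truth: synth.GroundTruth | None = None
    tumor_expr: pd.DataFrame | None = None


def _load_inputs(config: RunConfig):
    """Stage: input acquisition (synthetic generation or file reading)."""
    if config.synthetic is not None:
        scfg = config.synthetic
        net0 = synth.generate_interactome(scfg)
        pathways = synth.generate_pathways(scfg, net0)
        cohort = synth.generate_cohort(scfg, net0, pathways=pathways,
                                       seed=config.seed + scfg.seed)
        loc = synth.localization_table(net0)
        edges = list(net0.edges)
        return cohort, edges, loc, pathways
    if not config.inputs:
        raise ValueError("RunConfig needs either synthetic or inputs")
    paths = config.inputs
    required = ["beta", "probes", "expression", "samples", "segments",
                "mutations", "gene_coords", "edges", "localization"]
    for key in required:
        if key not in paths or not Path(paths[key]).exists():
            raise FileNotFoundError(f"preprocess stage: missing input '{key}'")
    samples = mio.read_sample_sheet(paths["samples"])
    cohort = synth.Cohort(
        cancer_type=str(samples["cancer_type"].iloc[0]) if "cancer_type" in samples else "NA",
        beta=mio.read_matrix(paths["beta"]),
        probe_annot=mio.read_probe_annotation(paths["probes"]),
        expr=mio.read_matrix(paths["expression"]),
        samples=samples,
        segments=mio.read_segments(paths["segments"]),
        mutations=mio.read_maf(paths["mutations"]),
        gene_coords=mio.read_gene_coords(paths["gene_coords"]),
        truth=None,
    )
    edges = mio.read_sif_edges(paths["edges"])
    loc = mio.read_localization(paths["localization"])
    pathways = mio.read_gmt(paths["gmt"]) if paths.get("gmt") else {}
    return cohort, edges, loc, pathways


def run_cancer_type(config: RunConfig) -> CancerBundle:
    """Run every per-cancer stage in order and (optionally) write the bundle."""
    cohort, edges, loc, pathways = _load_inputs(config)
    th = dd.DnamThresholds(config.fdr_max, config.min_delta_beta,
                           config.min_abs_log2fc)

    # network stage
    coarse = netmod.coarse_domains(loc)
    net = netmod.build_pruned_pin(edges, coarse)
    log.info("network: %s", netmod.network_stats(net))

    # preprocess stage
    beta = pp.clean_beta(cohort.beta, config.max_na_fraction, config.knn_k)
    meth = pp.gene_level_methylation(beta, cohort.probe_annot)
    expr = pp.normalize_expression(cohort.expr,
                                   already_log2=config.expression_scale == "log2")
    sample_order = cohort.samples["sample_id"].tolist()
    meth = meth[sample_order]
    expr = expr[sample_order]
    tumor_mask = (cohort.samples["group"] == "tumor").to_numpy()
    tumor_samples = cohort.samples.loc[tumor_mask.tolist(), "sample_id"].tolist()
    log.info("preprocess: %d probes -> %d genes methylation, %d genes expression",
             len(beta), len(meth), len(expr))

    # SCNA calling stage
    thresholds = sm.cn_thresholds(cohort.segments)
    call_matrix = sm.build_call_matrix(cohort.segments, thresholds,
                                       cohort.gene_coords)
    # genes x samples numeric CN covariate; samples without segments = Neutral
    cn_state = pd.DataFrame(0, index=expr.index, columns=expr.columns, dtype=np.int64)
    shared = call_matrix.index.intersection(cn_state.columns)
    common_genes = call_matrix.columns.intersection(cn_state.index)
    cn_state.loc[common_genes, shared] = call_matrix.loc[shared, common_genes].T

    # DNAm driver stage
    stats_df = dd.build_diff_stats(meth, expr, tumor_mask)
    sig = dd.call_dnam_de(stats_df, th)
    ranked = dd.classify_and_rank(sig)
    log.info("dnam: %d tested -> %d significant -> %d anti-correlated",
             len(stats_df), len(sig), len(ranked))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        multivar_dnam = dd.multivariate_filter(expr, meth, cn_state,
                                               genes=ranked.index)
    ranked = dd.filter_dnam_ranked(ranked, multivar_dnam, config.multivar_p)
    log.info("dnam: %d after multivariate filter", len(ranked))

    # SCNA/mutation ranking stage
    tails = sm.expression_tail_calls(expr)
    amp0, del0 = sm.rank_scna_genes(call_matrix, tails, tumor_samples)
    scna_genes = amp0.index.union(del0.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        multivar_scna = dd.multivariate_filter(
            expr, meth, cn_state, genes=scna_genes.intersection(meth.index))
    amp, dele = sm.rank_scna_genes(call_matrix, tails, tumor_samples,
                                   multivar=multivar_scna, p_max=config.multivar_p)
    log.info("scna: amp %d->%d, del %d->%d after multivariate filter",
             len(amp0), len(amp), len(del0), len(dele))
    mut = sm.rank_mutated_genes(cohort.mutations)

    top_lists = {
        "HyperM": ranked.loc[ranked["alteration_class"] == "HyperM"].index.tolist(),
        "HypoM": ranked.loc[ranked["alteration_class"] == "HypoM"].index.tolist(),
        "Amplification": amp.index.tolist(),
        "Deletion": dele.index.tolist(),
        "Mutation": mut.index.tolist(),
    }
    top_lists = {k: v[:config.top_k] for k, v in top_lists.items()}

    # topology stage
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        degree_table = netmod.degree_comparison(top_lists, net, config.top_k)
        pooled = netmod.pooled_degree_comparison(
            top_lists["HyperM"] + top_lists["HypoM"],
            top_lists["Amplification"] + top_lists["Deletion"], net)
        sp_table = netmod.shortest_path_comparison(top_lists, net, config.top_k)

    # enrichment stage
    annotated = [g for g in net.nodes if coarse.get(g)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enr_all = en.domain_enrichment_table(top_lists, coarse, annotated,
                                             "all-significant")
        nonempty = {k: v for k, v in top_lists.items() if v}
        enr_eq = (en.domain_enrichment_table(nonempty, coarse, annotated,
                                             "equalized")
                  if nonempty else pd.DataFrame())

    bundle = CancerBundle(
        cancer_type=cohort.cancer_type, config=config, net=net, coarse=coarse,
        pathways=pathways, diff_stats=stats_df, ranked_dnam=ranked,
        call_matrix=call_matrix, amp_ranked=amp, del_ranked=dele,
        mut_ranked=mut, top_lists=top_lists, degree_table=degree_table,
        pooled_degree_p=pooled, sp_table=sp_table, enrichment_all=enr_all,
        enrichment_equalized=enr_eq, truth=cohort.truth,
        tumor_expr=expr[tumor_samples],
    )
    if config.outdir:
        write_bundle(bundle, config.outdir)
    return bundle


def write_bundle(bundle: CancerBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hl = bundle.config.provenance()
    mio.write_matrix(bundle.ranked_dnam.rename_axis("gene"),
                     outdir / "ranked_dnam.tsv", hl)
    mio.write_matrix(bundle.amp_ranked.rename_axis("gene"),
                     outdir / "ranked_amplification.tsv", hl)
    mio.write_matrix(bundle.del_ranked.rename_axis("gene"),
                     outdir / "ranked_deletion.tsv", hl)
    mio.write_matrix(bundle.mut_ranked.rename_axis("gene"),
                     outdir / "ranked_mutation.tsv", hl)
    mio.write_matrix(bundle.call_matrix.rename_axis("sample"),
                     outdir / "cn_call_matrix.tsv", hl)
    mio.write_matrix(bundle.degree_table.rename_axis("class"),
                     outdir / "degree_comparison.tsv", hl)
    mio.write_matrix(bundle.sp_table, outdir / "shortest_path_comparison.tsv", hl)
    mio.write_matrix(bundle.enrichment_all, outdir / "domain_enrichment.tsv", hl)
    mio.write_matrix(bundle.enrichment_equalized,
                     outdir / "domain_enrichment_equalized.tsv", hl)
    stats = netmod.network_stats(bundle.net)
    stats["pooled_dnam_vs_cnv_degree_p"] = bundle.pooled_degree_p
    (outdir / "network_stats.json").write_text(
        pd.Series(stats).to_json(indent=2))


def altered_sets(bundle: CancerBundle) -> tuple[set, set]:
    """(DNAm-altered, SCNA-altered) gene sets of one bundle."""
    dn = set(bundle.top_lists["HyperM"]) | set(bundle.top_lists["HypoM"])
    sc = set(bundle.top_lists["Amplification"]) | set(bundle.top_lists["Deletion"])
    return dn, sc


def run_pan_cancer(bundles: list[CancerBundle], n_perm: int = 500,
                   enzymes: tuple[str, ...] | None = None,
                   outdir: str | Path | None = None) -> dict:
    """Pan-cancer meta-analysis over per-cancer bundles.

    Produces the pathway meta p-value table (Fisher's combined across
    types), the cumulative domain table, the deregulation-category matrix
    with its permutation consistency p, and (when enzyme genes are given or
    planted) tumor-only enzyme correlation labels.
    """
    if len(bundles) < 2:
        raise ValueError("need >=2 per-cancer bundles for a meta-analysis")
    universes = {frozenset(b.coarse) for b in bundles}
    if len(universes) > 1:
        raise ValueError("bundles have incompatible gene universes")
    first = bundles[0]
    per_type = {b.cancer_type: altered_sets(b) for b in bundles}
    meta = en.pathway_meta_table(first.pathways, per_type, first.coarse)
    cumulative = en.cumulative_domain_table(first.pathways, per_type, first.coarse)

    stats_by_type = {b.cancer_type: b.diff_stats for b in bundles}
    th = dd.DnamThresholds(first.config.fdr_max, first.config.min_delta_beta,
                           first.config.min_abs_log2fc)
    categories = cx.categorize_deregulation(stats_by_type, th)
    cons_p, cons_stat, at_floor = cx.consistency_empirical_p(
        categories, n_perm=n_perm, seed=first.config.seed)

    corr = None
    if enzymes is None and first.truth is not None and first.truth.enzymes:
        enzymes = tuple(first.truth.enzymes)
    if enzymes:
        expr_by_type = {b.cancer_type: b.tumor_expr for b in bundles
                        if b.tumor_expr is not None}
        targets = sorted(set().union(*(altered_sets(b)[0] for b in bundles)))
        if targets and expr_by_type:
            corr = cx.enzyme_correlation(expr_by_type, targets, enzymes)

    result = {"pathway_meta": meta, "cumulative_domain": cumulative,
              "categories": categories,
              "consistency_p": cons_p, "consistency_stat": cons_stat,
              "consistency_at_floor": at_floor, "enzyme_correlation": corr}
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hl = first.config.provenance()
        mio.write_matrix(meta.rename_axis("pathway"), outdir / "pathway_meta.tsv", hl)
        mio.write_matrix(cumulative, outdir / "cumulative_domain.tsv", hl)
        mio.write_matrix(categories, outdir / "deregulation_categories.tsv", hl)
        if corr is not None:
            mio.write_matrix(corr.set_index(["target", "enzyme"]),
                             outdir / "enzyme_correlation.tsv", hl)
        prefix = "<=" if at_floor else "="
        (outdir / "consistency.txt").write_text(
            f"empirical_p {prefix} {cons_p}\nstatistic = {cons_stat}\n")
    return result
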