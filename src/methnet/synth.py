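"""Synthetic multi-omic cohorts and interactomes with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* a connected scale-free-like interactome grown by preferential attachment,
  whose nodes carry signaling-domain labels and whose edges respect the
  signaling hierarchy (EC-EC, EC-MR, MR-IC, IC-IC) whenever a consistent
  partner exists;
* beta-valued methylation with probe-region structure (TSS200, first exon,
  TSS1500 and gene-body probes), modeled as logit-normal noise around
  group means;
* log2 expression with Gaussian noise, anti-correlated with promoter
  methylation for planted HyperM/HypoM genes;
* copy-number segments on a single linear pseudo-chromosome (genes tiled at
  10 kb spacing, 1-based inclusive coordinates) whose segmented means drive
  expression for planted Amplification/Deletion genes;
* mutation records, and GMT pathway sets optionally containing one planted
  EC-biased DNAm target pathway.

Planted gene classes are pairwise disjoint and, by default, domain-biased
(DNAm classes toward EC/MR nodes, SCNA classes toward IC nodes, odds 3:1),
so the expected topology and enrichment patterns can be planted and
recovered. A fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as mio
from .network import edge_allowed, fine_domains, largest_component

GENE_SPACING = 10_000
GENE_LENGTH = 5_000

# localization vocabularies consistent with the coarse-domain keyword lists
_TERMS = {
    "EC": ["Extracellular", "Secreted", "Cell junction"],
    "MR": ["Plasma membrane", "Cell surface", "Integral to membrane"],
    "IC": ["Nucleus", "Cytoplasm", "Cytosol"],
}

ALTERATION_CLASSES = ("HyperM", "HypoM", "Amplification", "Deletion", "Mutation")


@dataclass
class PlantedClass:
    """Size and placement bias of one planted alteration class."""
    n_genes: int = 20
    preferred_domains: tuple[str, ...] | None = None  # coarse labels
    domain_odds: float = 3.0
    degree_bias: str | None = None  # "low" | "high" | None


def default_planted() -> dict[str, PlantedClass]:
    return {
        "HyperM": PlantedClass(20, ("EC", "MR")),
        "HypoM": PlantedClass(20, ("EC", "MR")),
        "Amplification": PlantedClass(20, ("IC",)),
        "Deletion": PlantedClass(20, ("IC",)),
        "Mutation": PlantedClass(20, None),
    }


@dataclass
class SyntheticConfig:
    """Study conditions of one synthetic cohort/interactome.

    ``domain_fractions`` are proportions over the five fine domains
    (GM, SF, MR, ICRS, ICNRS); the generator draws coarse labels from the
    aggregated EC/MR/IC fractions and derives the fine split from realized
    receptor contact in the graph.
    """
    n_genes: int = 300
    n_probes_per_gene: dict = field(default_factory=lambda: {
        "TSS200": 2, "FirstExon": 1, "TSS1500": 2, "Body": 2})
    n_normal: int = 50
    n_tumor: int = 50
    cancer_types: list = field(default_factory=lambda: ["SYN1"])
    domain_fractions: tuple = (0.15, 0.10, 0.25, 0.25, 0.25)
    planted: dict = field(default_factory=default_planted)
    # effect sizes (the planted study conditions)
    delta_beta: float = 0.3
    log2fc: float = 2.0
    cn_shift: float = 1.0          # log2-ratio of planted CN events
    mutation_rate: float = 0.2     # tumor fraction mutated for planted genes
    cn_event_fraction: float = 0.6  # tumor fraction carrying a planted CN event
    # noise
    beta_logit_sd: float = 0.5
    expr_sd: float = 1.0
    bg_seg_sd: float = 0.08
    bg_mutation_rate: float = 0.005
    enzyme_coupling: float = 0.0   # latent-factor load tying enzymes to planted genes
    # interactome
    degree_model: dict = field(default_factory=lambda: {"m": 3, "power": 1.0})
    # pathways
    n_pathways: int = 15
    pathway_size: int = 40
    planted_pathway: bool = False
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.domain_fractions) - 1.0) > 1e-9:
            raise ValueError("domain_fractions must sum to 1")
        if len(self.domain_fractions) != 5:
            raise ValueError("domain_fractions needs 5 entries (GM,SF,MR,ICRS,ICNRS)")
        for name, value in [("n_genes", self.n_genes), ("n_normal", self.n_normal),
                            ("n_tumor", self.n_tumor)]:
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.delta_beta <= 1.0:
            raise ValueError("delta_beta must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted"] = {k: asdict(v) if isinstance(v, PlantedClass) else v
                        for k, v in self.planted.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        planted = {
            k: PlantedClass(**{**v, "preferred_domains":
                               tuple(v["preferred_domains"]) if v.get("preferred_domains") else None})
            if isinstance(v, dict) else v
            for k, v in d.get("planted", {}).items()}
        if planted:
            d["planted"] = planted
        if "domain_fractions" in d:
            d["domain_fractions"] = tuple(d["domain_fractions"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted alteration classes and per-gene domain assignments."""
    classes: dict            # class name -> sorted list of gene IDs
    coarse: dict             # gene -> EC/MR/IC
    fine: dict               # gene -> GM/SF/MR/ICRS/ICNRS
    enzymes: list = field(default_factory=list)

    def validate(self) -> None:
        four = [set(self.classes.get(c, ())) for c in
                ("HyperM", "HypoM", "Amplification", "Deletion")]
        for i in range(len(four)):
            for j in range(i + 1, len(four)):
                if four[i] & four[j]:
                    raise ValueError("planted DNAm/SCNA classes overlap")
        for c, genes in self.classes.items():
            missing = set(genes) - set(self.coarse)
            if missing:
                raise ValueError(f"{c}: planted genes missing from interactome")

    def to_json(self, path: str | Path) -> None:
        payload = {"classes": {k: sorted(v) for k, v in self.classes.items()},
                   "coarse": self.coarse, "fine": self.fine,
                   "enzymes": list(self.enzymes)}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# interactome


def generate_interactome(config: SyntheticConfig) -> nx.Graph:
    """Grow a connected, domain-labeled, hierarchy-consistent interactome.

    Nodes arrive one at a time and attach ``m`` edges to existing nodes with
    probability proportional to (degree+1)**power, restricted to
    hierarchy-consistent partners when any exist (all-MR configurations fall
    back to unrestricted attachment, producing prunable MR-MR edges).
    """
    config.validate()
    if config.n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(config.seed)
    f = config.domain_fractions
    coarse_p = np.array([f[0] + f[1], f[2], f[3] + f[4]])
    labels = rng.choice(["EC", "MR", "IC"], size=config.n_genes, p=coarse_p)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    coarse = dict(zip(genes, labels))

    m = int(config.degree_model.get("m", 3))
    power = float(config.degree_model.get("power", 1.0))
    g = nx.Graph()
    g.add_nodes_from(genes)
    deg = np.zeros(config.n_genes)
    # does any hierarchy-consistent partner exist at all for each label?
    has_global_partner = {
        lab: any(edge_allowed(lab, other) for other in set(labels))
        for lab in set(labels)}

    def _attach(i: int, existing: np.ndarray) -> None:
        ok = np.array([edge_allowed(labels[i], labels[j]) for j in existing])
        if ok.any():
            pool = existing[ok]
        elif not has_global_partner[labels[i]]:
            pool = existing       # degenerate label mix: violating edges allowed
        else:
            return                # consistent partners will arrive later
        w = (deg[pool] + 1.0) ** power
        picks = rng.choice(pool, size=min(m, pool.size), replace=False,
                           p=w / w.sum())
        for j in picks:
            g.add_edge(genes[i], genes[int(j)])
            deg[i] += 1
            deg[int(j)] += 1

    for i in range(1, config.n_genes):
        _attach(i, np.arange(i))
    for i in np.flatnonzero(deg == 0):   # early nodes skipped above
        others = np.array([j for j in range(config.n_genes) if j != i])
        _attach(int(i), others)
    try:
        g = largest_component(g)
    except ValueError:
        raise ValueError("n_genes/degree_model produced an empty interactome")

    terms = {}
    for gene in genes:
        if gene not in g:
            continue
        pick = rng.integers(0, len(_TERMS[coarse[gene]]))
        terms[gene] = {_TERMS[coarse[gene]][pick]}
    node_coarse = {n: coarse[n] for n in g.nodes}
    fine = fine_domains(node_coarse, g)
    nx.set_node_attributes(g, node_coarse, "coarse")
    nx.set_node_attributes(g, fine, "fine")
    nx.set_node_attributes(g, terms, "terms")
    return g


def localization_table(net: nx.Graph) -> dict[str, set[str]]:
    return {n: set(d["terms"]) for n, d in net.nodes(data=True)}


def generate_pathways(config: SyntheticConfig, net: nx.Graph,
                      ) -> dict[str, list[str]]:
    """Random gene sets; optionally one planted EC-rich target pathway.

    The planted pathway (name ``PATHWAY_PLANTED``) over-represents EC genes
    so that planting DNAm alterations on its EC members yields the
    differential-domain signal; all other pathways are uniform draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = sorted(net.nodes)
    coarse = nx.get_node_attributes(net, "coarse")
    out: dict[str, list[str]] = {}
    if config.planted_pathway:
        ec = [g for g in genes if coarse[g] == "EC"]
        ic = [g for g in genes if coarse[g] == "IC"]
        n_ec = min(len(ec), int(round(config.pathway_size * 0.4)))
        n_ic = min(len(ic), config.pathway_size - n_ec)
        members = list(rng.choice(ec, n_ec, replace=False)) + \
            list(rng.choice(ic, n_ic, replace=False))
        out["PATHWAY_PLANTED"] = sorted(members)
    while len(out) < config.n_pathways:
        name = f"PATHWAY_{len(out):02d}"
        size = min(config.pathway_size, len(genes))
        out[name] = sorted(rng.choice(genes, size, replace=False))
    return out


# ---------------------------------------------------------------------------
# cohort


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def select_planted(config: SyntheticConfig, net: nx.Graph,
                   rng: np.random.Generator,
                   pathways: dict[str, list[str]] | None = None) -> dict[str, list[str]]:
    """Draw pairwise-disjoint planted gene sets with domain/degree bias."""
    genes = np.array(sorted(net.nodes))
    coarse = nx.get_node_attributes(net, "coarse")
    degree = np.array([net.degree[g] for g in genes], dtype=float)
    available = np.ones(len(genes), dtype=bool)
    planted: dict[str, list[str]] = {}
    planted_pathway_ec = set()
    if config.planted_pathway and pathways and "PATHWAY_PLANTED" in pathways:
        planted_pathway_ec = {g for g in pathways["PATHWAY_PLANTED"]
                              if coarse.get(g) == "EC"}
    for cls in ALTERATION_CLASSES:
        spec = config.planted.get(cls)
        if spec is None or spec.n_genes == 0:
            planted[cls] = []
            continue
        if spec.n_genes > config.n_genes:
            raise ValueError(f"{cls}: planted class larger than gene universe")
        w = np.ones(len(genes))
        if spec.preferred_domains:
            pref = np.array([coarse.get(g) in spec.preferred_domains for g in genes])
            w[pref] *= spec.domain_odds
        if spec.degree_bias == "low":
            w *= 1.0 / (degree + 1.0)
        elif spec.degree_bias == "high":
            w *= degree + 1.0
        if cls == "HyperM" and planted_pathway_ec:
            inpw = np.array([g in planted_pathway_ec for g in genes])
            w[inpw] *= 50.0   # concentrate the DNAm signal in the target pathway
        w[~available] = 0.0
        if (w > 0).sum() < spec.n_genes:
            raise ValueError(f"{cls}: not enough available genes to plant")
        picks = rng.choice(len(genes), size=spec.n_genes, replace=False, p=w / w.sum())
        available[picks] = False
        planted[cls] = sorted(genes[picks])
    return planted


def gene_coordinates(net: nx.Graph) -> pd.DataFrame:
    """Tile genes on one pseudo-chromosome at 10 kb spacing (1-based)."""
    genes = sorted(net.nodes)
    starts = 1 + np.arange(len(genes)) * GENE_SPACING
    return pd.DataFrame({"gene": genes, "chrom": "chr1",
                         "start": starts, "end": starts + GENE_LENGTH - 1})


@dataclass
class Cohort:
    """One synthetic cancer type: all matrices plus the planted truth."""
    cancer_type: str
    beta: pd.DataFrame           # probes x samples
    probe_annot: pd.DataFrame
    expr: pd.DataFrame           # genes x samples, log2 scale
    samples: pd.DataFrame        # sample_id, group, cancer_type
    segments: pd.DataFrame
    mutations: pd.DataFrame
    gene_coords: pd.DataFrame
    truth: GroundTruth


def generate_cohort(config: SyntheticConfig, net: nx.Graph,
                    cancer_type: str | None = None, seed: int | None = None,
                    pathways: dict[str, list[str]] | None = None,
                    planted: dict[str, list[str]] | None = None) -> Cohort:
    """Simulate one cohort of matched methylation/expression/CNV/mutation data.

    Planted HyperM genes gain ``delta_beta`` promoter methylation and lose
    ``log2fc`` expression in tumors (HypoM mirrored); planted Amplification
    genes carry tumor segments with seg_mean >= ``cn_shift`` over the gene
    plus elevated expression in carrier tumors (Deletion mirrored); planted
    Mutation genes are mutated in >= ``mutation_rate`` of tumors. Non-planted
    genes have no systematic tumor/normal difference.
    """
    config.validate()
    cancer_type = cancer_type or config.cancer_types[0]
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 11]))
    genes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    coarse = nx.get_node_attributes(net, "coarse")
    fine = nx.get_node_attributes(net, "fine")

    if planted is None:
        planted = select_planted(config, net, rng, pathways)
    sets = {cls: set(v) for cls, v in planted.items()}

    # enzymes: two unplanted genes carrying the latent tumor factor
    enzymes: list[str] = []
    if config.enzyme_coupling > 0:
        taken = set().union(*sets.values()) if sets else set()
        free = [g for g in genes if g not in taken]
        enzymes = sorted(rng.choice(free, size=min(2, len(free)), replace=False))

    truth = GroundTruth(classes={k: sorted(v) for k, v in sets.items()},
                        coarse=dict(coarse), fine=dict(fine), enzymes=enzymes)
    truth.validate()

    normals = [f"{cancer_type}-N{i:03d}" for i in range(config.n_normal)]
    tumors = [f"{cancer_type}-T{i:03d}" for i in range(config.n_tumor)]
    samples = pd.DataFrame({
        "sample_id": normals + tumors,
        "group": ["normal"] * len(normals) + ["tumor"] * len(tumors),
        "cancer_type": cancer_type,
    })

    coords = gene_coordinates(net)

    # ---- probe table -----------------------------------------------------
    records = []
    pid = 0
    for g in genes:
        start = int(coords.loc[coords["gene"] == g, "start"].iloc[0])
        for region, count in config.n_probes_per_gene.items():
            offset = {"TSS200": 0, "FirstExon": 300, "TSS1500": 900, "Body": 2500}[region]
            for j in range(count):
                records.append((f"cg{pid:06d}", g, region, "chr1", start + offset + j * 40))
                pid += 1
    probe_annot = pd.DataFrame(records, columns=mio.PROBE_ANNOT_COLUMNS)

    # ---- methylation -----------------------------------------------------
    promoter_base = rng.uniform(0.15, 0.45, n_genes)
    for g in sorted(sets.get("HypoM", ())):   # leave room to subtract delta_beta
        promoter_base[idx[g]] = rng.uniform(0.45, 0.75)
    body_base = rng.uniform(0.4, 0.8, n_genes)
    delta = np.zeros(n_genes)
    for g in sorted(sets.get("HyperM", ())):
        delta[idx[g]] = config.delta_beta
    for g in sorted(sets.get("HypoM", ())):
        delta[idx[g]] = -config.delta_beta

    n_s = len(samples)
    tumor_mask = samples["group"].to_numpy() == "tumor"
    beta_rows = np.empty((len(probe_annot), n_s))
    clipped = False
    gi = probe_annot["gene"].map(idx).to_numpy()
    is_body = (probe_annot["region"] == "Body").to_numpy()
    probe_jitter = rng.normal(0, 0.02, len(probe_annot))
    for r in range(len(probe_annot)):
        base = body_base[gi[r]] if is_body[r] else promoter_base[gi[r]]
        means = np.full(n_s, base + probe_jitter[r])
        if not is_body[r]:
            means[tumor_mask] += delta[gi[r]]
        lo, hi = 0.01, 0.99
        if (means < lo).any() or (means > hi).any():
            clipped = True
        means = np.clip(means, lo, hi)
        beta_rows[r] = _expit(_logit(means) + rng.normal(0, config.beta_logit_sd, n_s))
    if clipped:
        warnings.warn("planted beta means clipped into [0.01, 0.99]")
    beta = pd.DataFrame(beta_rows, index=probe_annot["probe_id"].to_numpy(),
                        columns=samples["sample_id"].to_numpy())

    # ---- copy-number segments -------------------------------------------
    chrom_len = n_genes * GENE_SPACING + GENE_SPACING
    n_windows = max(20, n_genes // 5)   # mostly-neutral segmentation backbone
    bounds = np.linspace(1, chrom_len, n_windows + 1).astype(np.int64)
    seg_records = []
    amp_carriers: dict[str, np.ndarray] = {}
    del_carriers: dict[str, np.ndarray] = {}
    n_carry = max(1, int(round(config.cn_event_fraction * config.n_tumor)))
    for g in sorted(sets.get("Amplification", ())):
        amp_carriers[g] = rng.choice(config.n_tumor, n_carry, replace=False)
    for g in sorted(sets.get("Deletion", ())):
        del_carriers[g] = rng.choice(config.n_tumor, n_carry, replace=False)
    for ti, sample in enumerate(tumors):
        for w in range(n_windows):
            start, end = int(bounds[w]) + (w > 0), int(bounds[w + 1])
            seg_records.append((sample, "chr1", start, end,
                                max(2, (end - start) // 1000),
                                round(float(rng.normal(0, config.bg_seg_sd)), 4)))
        for g, carriers in amp_carriers.items():
            if ti in carriers:
                s = int(coords.loc[coords["gene"] == g, "start"].iloc[0])
                seg_records.append((sample, "chr1", max(1, s - 2000),
                                    s + GENE_LENGTH + 1999, 12,
                                    round(config.cn_shift + abs(float(rng.normal(0, 0.05))), 4)))
        for g, carriers in del_carriers.items():
            if ti in carriers:
                s = int(coords.loc[coords["gene"] == g, "start"].iloc[0])
                seg_records.append((sample, "chr1", max(1, s - 2000),
                                    s + GENE_LENGTH + 1999, 12,
                                    round(-config.cn_shift - abs(float(rng.normal(0, 0.05))), 4)))
    segments = pd.DataFrame(seg_records, columns=mio.SEG_COLUMNS)
    segments = segments.sort_values(["sample", "start"], kind="mergesort",
                                    ignore_index=True)

    # ---- expression ------------------------------------------------------
    base_expr = rng.normal(8.0, 2.0, n_genes)
    expr = base_expr[:, None] + rng.normal(0, config.expr_sd, (n_genes, n_s))
    for g in sorted(sets.get("HyperM", ())):
        expr[idx[g], tumor_mask] -= config.log2fc
    for g in sorted(sets.get("HypoM", ())):
        expr[idx[g], tumor_mask] += config.log2fc
    tumor_cols = np.flatnonzero(tumor_mask)
    for g, carriers in amp_carriers.items():
        expr[idx[g], tumor_cols[carriers]] += config.log2fc
    for g, carriers in del_carriers.items():
        expr[idx[g], tumor_cols[carriers]] -= config.log2fc
    if enzymes:
        factor = rng.normal(0, 1, tumor_cols.size)
        for e in enzymes:
            expr[idx[e], tumor_cols] += config.enzyme_coupling * factor
        for g in sorted(sets.get("HyperM", ())):
            expr[idx[g], tumor_cols] -= config.enzyme_coupling * factor
        for g in sorted(sets.get("HypoM", ())):
            expr[idx[g], tumor_cols] += config.enzyme_coupling * factor
    expr_df = pd.DataFrame(expr, index=genes, columns=samples["sample_id"].to_numpy())

    # ---- mutations -------------------------------------------------------
    mut_records = []
    for g in sorted(sets.get("Mutation", ())):
        n_mut = max(1, int(np.ceil(config.mutation_rate * config.n_tumor)))
        carriers = rng.choice(config.n_tumor, n_mut, replace=False)
        for ti in sorted(carriers):
            mut_records.append((g, tumors[ti], "Missense_Mutation"))
    background = rng.random((n_genes, config.n_tumor)) < config.bg_mutation_rate
    for r, c in zip(*np.nonzero(background)):
        klass = "Silent" if rng.random() < 0.3 else "Missense_Mutation"
        mut_records.append((genes[r], tumors[c], klass))
    mutations = pd.DataFrame(mut_records, columns=mio.MAF_COLUMNS)
    mutations = mutations.sort_values(["Hugo_Symbol", "Tumor_Sample_Barcode"],
                                      kind="mergesort", ignore_index=True)

    return Cohort(cancer_type, beta, probe_annot, expr_df, samples,
                  segments, mutations, coords, truth)


def generate_multi_cohorts(config: SyntheticConfig, net: nx.Graph,
                           pathways: dict[str, list[str]] | None = None,
                           ) -> dict[str, Cohort]:
    """One cohort per configured cancer-type label, with per-type subseeds."""
    out = {}
    for i, label in enumerate(config.cancer_types):
        out[label] = generate_cohort(config, net, cancer_type=label,
                                     seed=config.seed + 1000 * (i + 1),
                                     pathways=pathways)
    return out


# ---------------------------------------------------------------------------
# export


def write_cohort(cohort: Cohort, outdir: str | Path,
                 header_lines: list[str] | None = None) -> None:
    """Write every cohort artifact as plain TSV/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hl = header_lines or []
    mio.write_matrix(cohort.beta.rename_axis("probe_id"), outdir / "beta.tsv", hl)
    mio.write_matrix(cohort.expr.rename_axis("gene"), outdir / "expression.tsv", hl)
    cohort.probe_annot.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    cohort.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    cohort.segments.to_csv(outdir / "segments.seg.tsv", sep="\t", index=False)
    cohort.mutations.to_csv(outdir / "mutations.maf.tsv", sep="\t", index=False)
    cohort.gene_coords.to_csv(outdir / "gene_coords.tsv", sep="\t", index=False)
    cohort.truth.to_json(outdir / "ground_truth.json")


def write_interactome(net: nx.Graph, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_sif_edges(sorted(tuple(sorted(e)) for e in net.edges),
                        outdir / "interactome.sif.tsv")
    mio.write_localization(localization_table(net), outdir / "localization.tsv")
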