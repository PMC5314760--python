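"""Generator contracts: determinism, domain structure, planted effects."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from methnet import synth
from methnet import network as nm


class TestInteractome:
    def test_fixed_seed_reproducible(self):
        cfg = synth.SyntheticConfig(n_genes=100, seed=1)
        g1 = synth.generate_interactome(cfg)
        g2 = synth.generate_interactome(cfg)
        assert set(g1.edges) == set(g2.edges)
        assert nx.get_node_attributes(g1, "coarse") == \
            nx.get_node_attributes(g2, "coarse")

    def test_connected_simple_labeled(self, small_net):
        assert nx.is_connected(small_net)
        assert nx.number_of_selfloops(small_net) == 0
        for _, d in small_net.nodes(data=True):
            assert d["coarse"] in ("EC", "MR", "IC")
            assert d["fine"] in ("GM", "SF", "MR", "ICRS", "ICNRS")
            assert d["terms"]

    def test_edges_hierarchy_consistent_when_possible(self, small_net):
        coarse = nx.get_node_attributes(small_net, "coarse")
        for a, b in small_net.edges:
            assert nm.edge_allowed(coarse[a], coarse[b])

    def test_all_mr_graph_prunes_to_nothing(self):
        cfg = synth.SyntheticConfig(n_genes=30, domain_fractions=(0, 0, 1, 0, 0),
                                    seed=2)
        g = synth.generate_interactome(cfg)
        assert g.number_of_edges() > 0          # fallback attachment used
        coarse = nx.get_node_attributes(g, "coarse")
        assert set(coarse.values()) == {"MR"}
        assert nm.prune_edges(g, coarse).number_of_edges() == 0

    def test_higher_attachment_power_raises_degree_variance(self):
        vs = {p: [] for p in (0.0, 2.0)}
        for seed in range(20):
            for p in vs:
                cfg = synth.SyntheticConfig(
                    n_genes=80, seed=seed, degree_model={"m": 2, "power": p})
                g = synth.generate_interactome(cfg)
                vs[p].append(np.var([d for _, d in g.degree]))
        assert np.mean(vs[2.0]) > np.mean(vs[0.0])

    def test_localization_terms_recover_planted_domains(self, small_net):
        coarse = nm.coarse_domains(synth.localization_table(small_net))
        assert coarse == nx.get_node_attributes(small_net, "coarse")

    def test_too_few_genes_error(self):
        with pytest.raises(ValueError, match="n_genes"):
            synth.generate_interactome(synth.SyntheticConfig(n_genes=5))

    def test_bad_domain_fractions_error(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.SyntheticConfig(domain_fractions=(0.5, 0.5, 0.5, 0, 0)).validate()


class TestCohort:
    def test_ground_truth_disjoint_and_in_network(self, small_cohort, small_net):
        small_cohort.truth.validate()
        classes = [set(v) for v in small_cohort.truth.classes.values()]
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                assert not classes[i] & classes[j]
        for genes in classes:
            assert genes <= set(small_net.nodes)

    def test_beta_in_unit_interval_with_body_probes(self, small_cohort):
        b = small_cohort.beta.to_numpy()
        assert ((b >= 0) & (b <= 1)).all()
        assert (small_cohort.probe_annot["region"] == "Body").any()

    def test_segments_sorted_nonnegative(self, small_cohort):
        seg = small_cohort.segments
        assert (seg["end"] >= seg["start"]).all()
        for _, sub in seg.groupby("sample"):
            assert sub["start"].is_monotonic_increasing

    def test_planted_hyperm_shifts(self, small_config, small_cohort):
        truth = small_cohort.truth
        tumor = small_cohort.samples["group"] == "tumor"
        annot = small_cohort.probe_annot
        for g in truth.classes["HyperM"][:5]:
            probes = annot.loc[(annot["gene"] == g) & (annot["region"] == "TSS200"),
                               "probe_id"]
            vals = small_cohort.beta.loc[probes]
            diff = vals.loc[:, tumor.to_numpy()].mean(axis=1).mean() - \
                vals.loc[:, (~tumor).to_numpy()].mean(axis=1).mean()
            assert diff > small_config.delta_beta / 2
            lfc = small_cohort.expr.loc[g, tumor.to_numpy()].mean() - \
                small_cohort.expr.loc[g, (~tumor).to_numpy()].mean()
            assert lfc < -small_config.log2fc / 2

    def test_planted_amp_segments_cover_gene(self, small_config, small_cohort):
        coords = small_cohort.gene_coords.set_index("gene")
        seg = small_cohort.segments
        for g in small_cohort.truth.classes["Amplification"][:5]:
            s, e = coords.loc[g, ["start", "end"]]
            cover = seg[(seg["start"] <= e) & (seg["end"] >= s)
                        & (seg["seg_mean"] >= small_config.cn_shift)]
            frac = cover["sample"].nunique() / small_config.n_tumor
            assert frac >= small_config.cn_event_fraction - 1e-9

    def test_planted_mutation_rate(self, small_config, small_cohort):
        muts = small_cohort.mutations
        for g in small_cohort.truth.classes["Mutation"]:
            carriers = muts.loc[(muts["Hugo_Symbol"] == g)
                                & (muts["Variant_Classification"] != "Silent"),
                                "Tumor_Sample_Barcode"].nunique()
            assert carriers / small_config.n_tumor >= small_config.mutation_rate

    def test_overlapping_planted_sets_hard_error(self, small_config, small_net):
        genes = sorted(small_net.nodes)
        planted = {"HyperM": genes[:5], "HypoM": genes[:5],
                   "Amplification": [], "Deletion": [], "Mutation": []}
        with pytest.raises(ValueError, match="overlap"):
            synth.generate_cohort(small_config, small_net, planted=planted)

    def test_extreme_delta_beta_clips_with_warning(self, small_net):
        cfg = synth.SyntheticConfig(n_genes=150, n_normal=4, n_tumor=4,
                                    delta_beta=0.95, seed=3)
        with pytest.warns(UserWarning, match="clipped"):
            cohort = synth.generate_cohort(cfg, small_net)
        assert (cohort.beta.to_numpy() <= 1).all()

    def test_fixed_seed_byte_identical_files(self, tmp_path, small_config, small_net):
        import hashlib
        digests = []
        for run in ("a", "b"):
            c = synth.generate_cohort(small_config, small_net, seed=9)
            d = tmp_path / run
            synth.write_cohort(c, d)
            h = hashlib.sha256()
            for f in sorted(d.iterdir()):
                h.update(f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]


class TestPathways:
    def test_planted_pathway_is_ec_rich(self):
        cfg = synth.SyntheticConfig(n_genes=200, planted_pathway=True, seed=4)
        net = synth.generate_interactome(cfg)
        pws = synth.generate_pathways(cfg, net)
        assert "PATHWAY_PLANTED" in pws
        coarse = nx.get_node_attributes(net, "coarse")
        frac_ec = np.mean([coarse[g] == "EC" for g in pws["PATHWAY_PLANTED"]])
        overall = np.mean([c == "EC" for c in coarse.values()])
        assert frac_ec > overall

    def test_config_round_trip(self):
        cfg = synth.SyntheticConfig(planted_pathway=True, seed=11)
        again = synth.SyntheticConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()
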