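"""Moderated t, driver calling thresholds, integrative ranking, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methnet import dnam_drivers as dd


def _matrix(rows, n1=5, n2=5):
    df = pd.DataFrame(rows)
    mask = np.array([False] * n2 + [True] * n1)
    return df, mask


class TestModeratedT:
    def test_identical_group_means_zero_t(self, rng):
        x = rng.normal(0, 1, (20, 12))
        x[0] = np.tile(np.arange(6.0), 2)  # same values in both groups
        df = pd.DataFrame(x)
        mask = np.array([False] * 6 + [True] * 6)
        out = dd.moderated_t(df, mask)
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_prior_matches_ordinary_t(self, rng):
        x = rng.normal(0, 1, (50, 16))
        df = pd.DataFrame(x)
        mask = np.array([False] * 8 + [True] * 8)
        out = dd.moderated_t(df, mask, prior_df=0)
        # independent oracle: classical pooled-variance two-sample t
        ref = sps.ttest_ind(x[:, mask], x[:, ~mask], axis=1, equal_var=True)
        np.testing.assert_allclose(out["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(out["p"], ref.pvalue, rtol=1e-10)

    def test_null_type_i_error_calibrated(self, rng):
        x = rng.normal(0, 1, (2000, 40))
        mask = np.array([False] * 20 + [True] * 20)
        out = dd.moderated_t(pd.DataFrame(x), mask)
        frac = (out["p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_shrinkage_pulls_variances_together(self, rng):
        # genes with wildly different sample variances: moderated |t| of the
        # low-variance gene is damped relative to its ordinary |t|
        x = rng.normal(0, 1, (200, 20))
        x[0] *= 0.05
        x[0, 10:] += 0.2
        mask = np.array([False] * 10 + [True] * 10)
        mod = dd.moderated_t(pd.DataFrame(x), mask)
        ord_ = dd.moderated_t(pd.DataFrame(x), mask, prior_df=0)
        assert abs(mod["t"].iloc[0]) < abs(ord_["t"].iloc[0])

    def test_needs_two_per_group(self):
        df = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError, match=">=2 samples"):
            dd.moderated_t(df, np.array([True, True, False]))


class TestCallAndRank:
    @pytest.mark.parametrize("fdr_m,db,fdr_e,lfc,kept", [
        (0.04, 0.15, 0.01, -1.5, True),   # passes every threshold
        (0.04, 0.05, 0.01, -1.5, False),  # |delta beta| below 0.1
        (0.06, 0.30, 0.01, -1.5, False),  # methylation FDR above 0.05
        (0.04, 0.15, 0.01, -0.5, False),  # |log2FC| below 1
    ])
    def test_threshold_gate(self, fdr_m, db, fdr_e, lfc, kept):
        stats_df = pd.DataFrame({
            "fdr_meth": [fdr_m], "delta_beta": [db],
            "fdr_expr": [fdr_e], "log2fc": [lfc],
            "t_meth": [3.0], "t_expr": [-3.0],
        }, index=["g"])
        out = dd.call_dnam_de(stats_df)
        assert ("g" in out.index) == kept

    def test_raising_fdr_never_shrinks_set(self, rng):
        n = 200
        stats_df = pd.DataFrame({
            "fdr_meth": rng.uniform(0, 0.2, n), "delta_beta": rng.uniform(-0.5, 0.5, n),
            "fdr_expr": rng.uniform(0, 0.2, n), "log2fc": rng.uniform(-3, 3, n),
            "t_meth": rng.normal(0, 3, n), "t_expr": rng.normal(0, 3, n)})
        lo = dd.call_dnam_de(stats_df, dd.DnamThresholds(fdr_max=0.05))
        hi = dd.call_dnam_de(stats_df, dd.DnamThresholds(fdr_max=0.15))
        assert set(lo.index) <= set(hi.index)

    @pytest.mark.parametrize("tm,te,cls,score", [
        (4.0, -3.0, "HyperM", 3.5),
        (-2.0, 5.0, "HypoM", 3.5),
        (3.0, 2.0, None, None),   # same-sign: discarded
    ])
    def test_classification_and_score(self, tm, te, cls, score):
        stats_df = pd.DataFrame({
            "t_meth": [tm, 1.0, -1.0], "t_expr": [te, -1.0, 1.0],
            "fdr_meth": 0.01, "fdr_expr": 0.01,
            "delta_beta": [0.2, 0.2, -0.2], "log2fc": [-2.0, -2.0, 2.0]},
            index=["g", "h1", "h2"])
        ranked = dd.classify_and_rank(stats_df)
        if cls is None:
            assert "g" not in ranked.index
        else:
            assert ranked.loc["g", "alteration_class"] == cls
            assert ranked.loc["g", "score"] == pytest.approx(score)

    def test_classes_disjoint_and_scores_sorted(self, rng):
        n = 100
        stats_df = pd.DataFrame({
            "t_meth": rng.normal(0, 3, n), "t_expr": rng.normal(0, 3, n),
            "fdr_meth": 0.01, "fdr_expr": 0.01,
            "delta_beta": rng.uniform(-0.5, 0.5, n), "log2fc": rng.normal(0, 2, n)},
            index=[f"g{i}" for i in range(n)])
        ranked = dd.classify_and_rank(stats_df)
        hyper = ranked[ranked["alteration_class"] == "HyperM"]
        hypo = ranked[ranked["alteration_class"] == "HypoM"]
        assert not (set(hyper.index) & set(hypo.index))
        for sub in (hyper, hypo):
            assert (np.diff(sub["score"]) <= 1e-12).all()
            assert list(sub["rank"]) == list(range(1, len(sub) + 1))


class TestMultivariateFilter:
    def test_methylation_driven_gene_kept(self, rng):
        n = 60
        meth = rng.uniform(0.1, 0.9, n)
        expr = 10 - 8 * meth + rng.normal(0, 0.5, n)
        cols = [f"s{i}" for i in range(n)]
        res = dd.multivariate_filter(
            pd.DataFrame([expr], index=["g"], columns=cols),
            pd.DataFrame([meth], index=["g"], columns=cols),
            pd.DataFrame([np.zeros(n)], index=["g"], columns=cols))
        assert res.loc["g", "coef_dnam"] < 0 and res.loc["g", "p_dnam"] < 0.05

    def test_cn_driven_gene_dropped_from_dnam_list(self, rng):
        n = 60
        cn = rng.choice([-1, 0, 1, 2], n).astype(float)
        meth = rng.uniform(0.1, 0.9, n)
        expr = 2 * cn + rng.normal(0, 0.5, n)
        cols = [f"s{i}" for i in range(n)]
        res = dd.multivariate_filter(
            pd.DataFrame([expr], index=["g"], columns=cols),
            pd.DataFrame([meth], index=["g"], columns=cols),
            pd.DataFrame([cn], index=["g"], columns=cols))
        dnam_ok = (res["coef_dnam"] < 0) & (res["p_dnam"] < 0.05)
        assert not dnam_ok.loc["g"]
        assert res.loc["g", "coef_cnv"] > 0 and res.loc["g", "p_cnv"] < 0.05

    def test_constant_methylation_dropped_with_warning(self, rng):
        n = 20
        cols = [f"s{i}" for i in range(n)]
        with pytest.warns(UserWarning, match="constant covariate"):
            res = dd.multivariate_filter(
                pd.DataFrame([rng.normal(0, 1, n)], index=["g"], columns=cols),
                pd.DataFrame([np.full(n, 0.5)], index=["g"], columns=cols),
                pd.DataFrame([np.zeros(n)], index=["g"], columns=cols))
        assert "g" not in res.index


class TestTissueSpecific:
    def _cohort(self, rng, delta_beta, log2fc):
        n1, n2, g = 10, 30, 50
        mask = np.array([True] * n1 + [False] * n2)
        meth = rng.uniform(0.3, 0.5, (g, n1 + n2))
        expr = rng.normal(8, 0.5, (g, n1 + n2))
        meth[0, :n1] += delta_beta
        expr[0, :n1] += log2fc
        cols = [f"s{i}" for i in range(n1 + n2)]
        return (pd.DataFrame(meth, index=[f"g{i}" for i in range(g)], columns=cols),
                pd.DataFrame(expr, index=[f"g{i}" for i in range(g)], columns=cols),
                mask)

    def test_strong_tissue_gene_called_hyperm(self, rng):
        meth, expr, mask = self._cohort(rng, 0.35, -2.5)
        out = dd.tissue_specific_genes(meth, expr, mask)
        assert out.loc["g0", "alteration_class"] == "HyperM"

    def test_weak_delta_beta_dropped(self, rng):
        meth, expr, mask = self._cohort(rng, 0.2, -2.5)
        out = dd.tissue_specific_genes(meth, expr, mask)
        assert "g0" not in out.index

    def test_empty_result_allowed(self, rng):
        meth, expr, mask = self._cohort(rng, 0.0, 0.0)
        out = dd.tissue_specific_genes(meth, expr, mask)
        assert len(out) == 0
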