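"""CN thresholds, call matrix vs brute-force oracle, tails, rankings."""

import numpy as np
import pandas as pd
import pytest

from methnet import scna_mut as sm


def _seg(sample, chrom, start, end, mean, n_probes=10):
    return {"sample": sample, "chrom": chrom, "start": start, "end": end,
            "num_probes": n_probes, "seg_mean": mean}


class TestThresholds:
    def test_symmetric_values_direct_formula(self):
        # median 0; central half = {-0.25, 0, 0.25}, sample sd exactly 0.25
        seg = pd.DataFrame([_seg("s", "chr1", i * 10 + 1, i * 10 + 9, v)
                            for i, v in enumerate([-5, -0.25, 0, 0.25, 5])])
        seg["num_probes"] = 1
        th = sm.cn_thresholds(seg)["s"]
        assert th.median == pytest.approx(0.0)
        assert th.sigma == pytest.approx(0.25)
        assert (th.gain, th.amp, th.loss, th.deletion) == \
            pytest.approx((0.5, 1.0, -0.5, -1.0))

    def test_location_equivariance(self):
        vals = [-5, -0.25, 0, 0.25, 5]
        base = pd.DataFrame([_seg("s", "chr1", i * 10 + 1, i * 10 + 9, v, 1)
                             for i, v in enumerate(vals)])
        shifted = base.assign(seg_mean=base["seg_mean"] + 0.7)
        t0 = sm.cn_thresholds(base)["s"]
        t1 = sm.cn_thresholds(shifted)["s"]
        assert t1.median == pytest.approx(t0.median + 0.7)
        assert t1.gain == pytest.approx(t0.gain + 0.7)
        assert t1.amp == pytest.approx(t0.amp + 0.7)

    def test_constant_values_all_neutral(self):
        seg = pd.DataFrame([_seg("s", "chr1", i * 10 + 1, i * 10 + 9, 0.3, 1)
                            for i in range(6)])
        with pytest.warns(UserWarning, match="zero noise"):
            th = sm.cn_thresholds(seg)["s"]
        assert th.call(0.3) == 0 and th.call(0.2999) == 0 and th.call(0.3001) == 0


def _oracle_call_matrix(seg, thresholds, coords):
    """Brute force: enumerate all overlapping segments per (sample, gene)."""
    samples = sorted(thresholds)
    out = pd.DataFrame(0, index=samples, columns=coords["gene"], dtype=np.int64)
    for sample in samples:
        th = thresholds[sample]
        for _, g in coords.iterrows():
            best_state, best_sev, best_abs = 0, 0, -1.0
            for _, s in seg[seg["sample"] == sample].iterrows():
                if s["chrom"] != g["chrom"]:
                    continue
                if s["start"] > g["end"] or s["end"] < g["start"]:
                    continue
                state = th.call(s["seg_mean"])
                sev, mag = abs(state), abs(s["seg_mean"])
                if sev > best_sev or (sev == best_sev and sev > 0 and mag > best_abs):
                    best_state, best_sev, best_abs = state, sev, mag
            out.loc[sample, g["gene"]] = best_state
    return out


class TestCallMatrix:
    TH = {"s": sm.CNThresholds(median=0.0, sigma=0.3)}
    COORDS = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"],
                           "start": [100], "end": [200]})

    def test_amp_segment_called_amplification(self):
        seg = pd.DataFrame([_seg("s", "chr1", 50, 300, 1.5)])
        out = sm.build_call_matrix(seg, self.TH, self.COORDS)
        assert out.loc["s", "g"] == 2

    def test_maximal_severity_wins(self):
        seg = pd.DataFrame([_seg("s", "chr1", 50, 150, 0.1),     # Neutral
                            _seg("s", "chr1", 151, 300, 0.8)])   # Gain
        out = sm.build_call_matrix(seg, self.TH, self.COORDS)
        assert out.loc["s", "g"] == 1

    def test_equal_severity_tie_breaks_by_abs_seg_mean(self):
        # Gain (+0.8) vs Loss (-1.1): both severity 1 here, |−1.1| wins
        seg = pd.DataFrame([_seg("s", "chr1", 50, 150, 0.8),
                            _seg("s", "chr1", 151, 300, -1.1)])
        out = sm.build_call_matrix(seg, self.TH, self.COORDS)
        assert out.loc["s", "g"] == -1

    def test_no_overlap_neutral(self):
        seg = pd.DataFrame([_seg("s", "chr2", 50, 300, 1.5),
                            _seg("s", "chr1", 500, 900, 1.5)])
        out = sm.build_call_matrix(seg, self.TH, self.COORDS)
        assert out.loc["s", "g"] == 0

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        th = {"a": sm.CNThresholds(0.0, 0.25), "b": sm.CNThresholds(0.1, 0.2)}
        for _ in range(200):
            coords = pd.DataFrame({
                "gene": [f"g{i}" for i in range(5)],
                "chrom": rng.choice(["chr1", "chr2"], 5),
                "start": rng.integers(1, 500, 5)})
            coords["end"] = coords["start"] + rng.integers(1, 200, 5)
            segs = []
            for s in th:
                for _ in range(rng.integers(1, 7)):
                    start = int(rng.integers(1, 600))
                    segs.append(_seg(s, str(rng.choice(["chr1", "chr2"])),
                                     start, start + int(rng.integers(0, 300)),
                                     float(rng.normal(0, 0.8))))
            seg = pd.DataFrame(segs)
            got = sm.build_call_matrix(seg, th, coords)
            want = _oracle_call_matrix(seg, th, coords)
            pd.testing.assert_frame_equal(got, want, check_names=False)

    def test_severity_escalation_never_decreases_magnitude(self, rng):
        # replacing an overlapping segment's value by a strictly more severe
        # one never decreases |state|
        th = {"s": sm.CNThresholds(0.0, 0.25)}
        coords = self.COORDS
        seg = pd.DataFrame([_seg("s", "chr1", 50, 300, 0.6),
                            _seg("s", "chr1", 120, 180, -0.6)])
        base = abs(sm.build_call_matrix(seg, th, coords).loc["s", "g"])
        seg2 = seg.assign(seg_mean=[0.6, -1.5])   # escalate loss -> deletion
        esc = abs(sm.build_call_matrix(seg2, th, coords).loc["s", "g"])
        assert esc >= base


class TestExpressionTails:
    def test_hand_constructed_flags(self):
        row = np.array([0.0] * 10 + [5.0, -5.0])
        expr = pd.DataFrame([row, row * 0 + 1.0 * np.arange(12)])
        out = sm.expression_tail_calls(expr)
        assert out.iloc[0, 10] == 1 and out.iloc[0, 11] == -1
        assert (out.iloc[0, :10] == 0).all()

    def test_value_at_mean_is_none_and_zero_variance_no_calls(self):
        expr = pd.DataFrame([[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 2.0]])
        out = sm.expression_tail_calls(expr)
        assert (out.iloc[0] == 0).all()          # sigma = 0: no calls
        assert out.iloc[1, 1] == 0               # exactly at the mean

    def test_tail_fraction_five_percent(self, rng):
        x = rng.normal(0, 1, (50, 10000))
        out = sm.expression_tail_calls(pd.DataFrame(x))
        frac_under = (out.to_numpy() == -1).mean()
        assert 0.04 <= frac_under <= 0.06


class TestRankings:
    def test_joint_count_ordering_and_exclusions(self):
        samples = [f"s{i}" for i in range(12)]
        calls = pd.DataFrame(0, index=samples, columns=["a", "b", "c"])
        tails = pd.DataFrame(0, index=["a", "b", "c"], columns=samples)
        calls.loc[samples[:10], "a"] = 2
        tails.loc["a", samples[:10]] = 1          # 10 joint amp events
        calls.loc[samples[:5], "b"] = 2
        tails.loc["b", samples[:5]] = 1           # 5 joint amp events
        calls.loc[samples, "c"] = 2               # amplified, never over
        amp, dele = sm.rank_scna_genes(calls, tails)
        assert list(amp.index) == ["a", "b"]
        assert list(amp["rank"]) == [1, 2]
        assert "c" not in amp.index and len(dele) == 0

    def test_empty_cohort_two_empty_lists(self):
        calls = pd.DataFrame(dtype=np.int64)
        tails = pd.DataFrame(dtype=np.int64)
        amp, dele = sm.rank_scna_genes(calls, tails)
        assert len(amp) == 0 and len(dele) == 0

    def test_mutation_frequency_ranking(self):
        muts = pd.DataFrame({
            "Hugo_Symbol": ["m1"] * 3 + ["m2"] * 2 + ["m3"] + ["m1"],
            "Tumor_Sample_Barcode": ["t1", "t2", "t3", "t1", "t2", "t1", "t1"],
            "Variant_Classification": ["Missense_Mutation"] * 5 + ["Silent",
                                                                   "Missense_Mutation"],
        })
        out = sm.rank_mutated_genes(muts)
        assert list(out.index) == ["m1", "m2"]     # m3 only silent: excluded
        assert out.loc["m1", "score"] == 3          # t1 counted once
        assert out.loc["m2", "score"] == 2
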