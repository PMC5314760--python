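"""Copy-number call matrices, joint SCNA+expression rankings, mutation ranking.

Per-sample copy-number states are called from segmented log2 ratios against
sample-specific thresholds: with m the (probe-weighted) median of the
sample's segment means and sigma the standard deviation of the 50% of
values nearest m (the noise half), gains/losses are called beyond m ± 2σ
and amplifications/deletions beyond m ± 4σ. Gene states come from
maximal-severity overlap of segments with gene intervals (1-based
inclusive; ties between a loss-type and gain-type state of equal severity
break by larger |seg_mean|). The Amplification (Deletion) driver list
counts, per gene, tumors where an amplification (deletion) coincides with
expression in the 5% right (left) Gaussian tail of that gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STATE_NAMES = {-2: "Deletion", -1: "Loss", 0: "Neutral", 1: "Gain", 2: "Amplification"}
Z_95 = 1.6449  # standard-normal 95th percentile


@dataclass(frozen=True)
class CNThresholds:
    """Per-sample copy-number calling thresholds."""
    median: float
    sigma: float

    @property
    def gain(self) -> float:
        return self.median + 2 * self.sigma

    @property
    def loss(self) -> float:
        return self.median - 2 * self.sigma

    @property
    def amp(self) -> float:
        return self.median + 4 * self.sigma

    @property
    def deletion(self) -> float:
        return self.median - 4 * self.sigma

    def call(self, seg_mean: float) -> int:
        if self.sigma == 0:
            return 0   # collapsed thresholds: everything Neutral
        if seg_mean > self.amp:
            return 2
        if seg_mean < self.deletion:
            return -2
        if seg_mean > self.gain:
            return 1
        if seg_mean < self.loss:
            return -1
        return 0


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cutoff = 0.5 * w.sum()
    return float(v[np.searchsorted(cum, cutoff)])


def cn_thresholds(seg: pd.DataFrame) -> dict[str, CNThresholds]:
    """Fit per-sample thresholds from a segment table.

    sigma is estimated on the noise half: the 50% of segment values with the
    smallest |value − median|. With sigma = 0 all thresholds collapse to the
    median and every downstream call is Neutral (warned).
    """
    out: dict[str, CNThresholds] = {}
    for sample, sub in seg.groupby("sample", sort=True):
        values = sub["seg_mean"].to_numpy(dtype=float)
        if len(values) < 4:
            raise ValueError(f"sample {sample}: need >=4 segment values")
        weights = (sub["num_probes"].to_numpy(dtype=float)
                   if "num_probes" in sub and sub["num_probes"].notna().all()
                   else np.ones_like(values))
        m = _weighted_median(values, weights)
        k = int(np.ceil(len(values) / 2))
        central = values[np.argsort(np.abs(values - m), kind="stable")[:k]]
        sigma = float(np.std(central, ddof=1)) if k > 1 else 0.0
        if sigma == 0:
            warnings.warn(f"sample {sample}: zero noise scale; all calls Neutral")
        out[sample] = CNThresholds(median=m, sigma=sigma)
    return out


def build_call_matrix(seg: pd.DataFrame, thresholds: dict[str, CNThresholds],
                      gene_coords: pd.DataFrame) -> pd.DataFrame:
    """samples x genes matrix of states in {-2, -1, 0, 1, 2}.

    Per (sample, gene) the state of maximal severity among overlapping
    segments is assigned; equal-severity sign conflicts resolve to the
    segment with the larger |seg_mean|. No overlap means Neutral.
    """
    genes = gene_coords["gene"].to_numpy()
    g_chrom = gene_coords["chrom"].to_numpy()
    g_start = gene_coords["start"].to_numpy(dtype=np.int64)
    g_end = gene_coords["end"].to_numpy(dtype=np.int64)
    samples = sorted(thresholds)
    calls = np.zeros((len(samples), len(genes)), dtype=np.int64)
    for si, sample in enumerate(samples):
        th = thresholds[sample]
        sub = seg[seg["sample"] == sample]
        if sub.empty:
            continue
        s_chrom = sub["chrom"].to_numpy()
        s_start = sub["start"].to_numpy(dtype=np.int64)
        s_end = sub["end"].to_numpy(dtype=np.int64)
        s_mean = sub["seg_mean"].to_numpy(dtype=float)
        s_state = np.array([th.call(v) for v in s_mean], dtype=np.int64)
        for chrom in np.unique(s_chrom):
            smask = s_chrom == chrom
            gmask = g_chrom == chrom
            if not gmask.any():
                continue
            # overlap of 1-based inclusive intervals: start_s <= end_g and end_s >= start_g
            ov = ((s_start[smask][:, None] <= g_end[gmask][None, :])
                  & (s_end[smask][:, None] >= g_start[gmask][None, :]))
            st = s_state[smask]
            mn = s_mean[smask]
            gidx = np.flatnonzero(gmask)
            for col, gi in enumerate(gidx):
                hits = np.flatnonzero(ov[:, col])
                if hits.size == 0:
                    continue
                sev = np.abs(st[hits])
                top = hits[sev == sev.max()]
                if sev.max() == 0:
                    continue
                best = top[np.argmax(np.abs(mn[top]))]
                calls[si, gi] = st[best]
    return pd.DataFrame(calls, index=samples, columns=genes)


def expression_tail_calls(expr: pd.DataFrame) -> pd.DataFrame:
    """Flag extreme expression per (gene, sample): -1 under, 0 none, +1 over.

    A Gaussian is fitted per gene by maximum likelihood over all samples of
    the cancer type; values strictly beyond mu ± 1.6449·sigma fall in the 5%
    tails. Genes with zero variance get no calls.
    """
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need >=3 samples to fit expression tails")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)  # MLE sigma
    flags = np.zeros_like(x, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        flags[x < mu - Z_95 * sd] = -1
        flags[x > mu + Z_95 * sd] = 1
    flags[sd[:, 0] == 0, :] = 0
    return pd.DataFrame(flags, index=expr.index, columns=expr.columns)


def joint_call_matrices(calls: pd.DataFrame, tails: pd.DataFrame,
                        tumor_samples=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary Amplification∧Overexpression and Deletion∧Underexpression matrices.

    ``calls`` is samples x genes, ``tails`` genes x samples; both restricted
    to shared samples/genes (optionally intersected with ``tumor_samples``).
    """
    samples = calls.index.intersection(tails.columns)
    if tumor_samples is not None:
        samples = samples.intersection(pd.Index(tumor_samples))
    genes = calls.columns.intersection(tails.index)
    c = calls.loc[samples, genes].to_numpy()
    t = tails.loc[genes, samples].to_numpy().T
    amp = pd.DataFrame(((c == 2) & (t == 1)).astype(np.int64), index=samples, columns=genes)
    dele = pd.DataFrame(((c == -2) & (t == -1)).astype(np.int64), index=samples, columns=genes)
    return amp, dele


def rank_joint_genes(joint: pd.DataFrame, alteration_class: str) -> pd.DataFrame:
    """Rank genes by the number of joint events, descending; ties by gene ID."""
    counts = joint.sum(axis=0)
    counts = counts[counts > 0]
    out = (counts.rename("score").rename_axis("gene").reset_index()
                 .sort_values(["score", "gene"], ascending=[False, True],
                              kind="mergesort"))
    out["alteration_class"] = alteration_class
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("gene")


def rank_scna_genes(calls: pd.DataFrame, tails: pd.DataFrame,
                    tumor_samples=None,
                    multivar: pd.DataFrame | None = None,
                    p_max: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amplification and Deletion ranked lists from joint SCNA+expression calls.

    When multivariate regression results are supplied, only genes whose
    copy-number coefficient is significantly positive survive (the
    expression change must track the copy-number state).
    """
    amp_m, del_m = joint_call_matrices(calls, tails, tumor_samples)
    amp = rank_joint_genes(amp_m, "Amplification")
    dele = rank_joint_genes(del_m, "Deletion")
    if multivar is not None:
        if multivar.empty:
            ok = pd.Index([])
        else:
            ok = multivar.index[(multivar["coef_cnv"] > 0) & (multivar["p_cnv"] < p_max)]
        amp = amp.loc[amp.index.intersection(ok)].sort_values("rank")
        dele = dele.loc[dele.index.intersection(ok)].sort_values("rank")
        amp["rank"] = np.arange(1, len(amp) + 1)
        dele["rank"] = np.arange(1, len(dele) + 1)
    return amp, dele


def rank_mutated_genes(muts: pd.DataFrame,
                       silent_classes: tuple[str, ...] = ("Silent",)) -> pd.DataFrame:
    """Rank genes by the number of distinct samples with a non-silent mutation."""
    nonsilent = muts[~muts["Variant_Classification"].isin(silent_classes)]
    counts = (nonsilent.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"]
                        .nunique().rename("score"))
    counts = counts[counts > 0]
    out = (counts.rename_axis("gene").reset_index()
                 .sort_values(["score", "gene"], ascending=[False, True],
                              kind="mergesort"))
    out["alteration_class"] = "Mutation"
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("gene")
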