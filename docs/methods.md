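# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions and the design choices behind `methnet`. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Preprocessing

**Methylation.** Probes missing in more than `max_na_fraction` (default
0.3) of samples are removed; remaining missing values are imputed by
k-nearest-neighbour averaging (default k = 5). Neighbours are probes
(rows), ranked by Euclidean distance over pairwise-complete samples and
normalized by the number of shared samples; only neighbours observed at the
missing sample donate, and when fewer than k exist all available donors are
used with a warning. Probe-wise (rather than sample-wise) imputation is the
convention of the standard knn-imputation procedure for arrays; the
orientation is switchable via `axis="samples"`.

Gene-level promoter methylation is the mean beta of TSS200 probes, else
first-exon probes, else TSS1500 probes; genes with only gene-body probes
are silently absent, and body probes never contribute. The output is
therefore always a convex combination of probe betas and stays in [0, 1].
A probe annotated to several genes contributes to each independently.

**Expression.** Zeros are replaced by the minimum positive value of the
whole matrix, values are log2-transformed, and columns are
quantile-normalized to the mean of the per-column sorted values
(the standard between-array normalization). Ties receive the mean of the
quantile targets their sorted positions span, so permutation-equal columns
map to identical outputs. Matrices already on the log2 scale (e.g. the
synthetic cohorts) skip the zero/log step via `already_log2=True`.

## Moderated t and driver calling

The two-group comparison uses an empirical-Bayes moderated t. Per gene,
the pooled variance s²_g has d_g = n₁ + n₂ − 2 degrees of freedom. A scaled
inverse-χ² prior (d₀, s₀²) is fitted across genes by method of moments on
z = log s²_g: the excess variance of z over the χ² sampling contribution
trigamma(d_g/2) determines d₀ through a trigamma inversion (Newton
iteration), and s₀² follows from the mean of z with the digamma bias
correction. When the observed spread of z is no larger than sampling noise,
d₀ = ∞ and all genes share s₀². The posterior variance is
s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g) and p-values use t with d_g + d₀ df.
`prior_df=0` recovers the ordinary pooled-variance t exactly, which the
tests exploit as an oracle. Positive t means tumor > normal.

Driver thresholds (defaults, all configurable in `RunConfig`): FDR < 0.05
per data type (Benjamini–Hochberg within data type and cancer type),
|Δβ| > 0.1, |log₂FC| > 1; tissue-specific lists use |Δβ| > 0.3 and
|log₂FC| > 2 on normals only. Only anti-correlated genes are classified
(HyperM: t_meth > 0 ∧ t_expr < 0; HypoM mirrored); same-sign genes are
discarded by design — positively-correlated promoter methylation/expression
patterns are a minority and less plausibly causal, and are an explicit
non-goal.

**Integrative ranking.** The score S = (|t_meth| + |t_expr|)/2, with ties
broken by larger |t_expr| and then gene ID. The referenced integrative
statistic is not fully specified in the source material; the mean of
absolute moderated t's was chosen because it is symmetric in the two
evidence channels and monotone in each. The strategy lives in one function
(`classify_and_rank`) and can be swapped.

**Multivariate filter.** Per gene, OLS of log₂ expression on gene-level
methylation and the numeric copy-number state {−2…+2} over *all* samples
(normals carry Neutral). DNAm lists keep genes with a significantly
negative methylation coefficient, SCNA lists genes with a significantly
positive copy-number coefficient; p < 0.05 (the source states only
"statistical significance"). Ordinary rather than robust regression is
used — the named framework's default. Genes with a constant covariate are
dropped with a warning.

## Copy-number calling

Per sample, m is the probe-weighted median of segment log₂ ratios
(unweighted when probe counts are absent) and σ is the standard deviation
(ddof = 1) of the ⌈n/2⌉ segment values nearest m. "Top 50% of the probes
ordered by their log ratios" is interpreted as this noise half nearest the
median — a robust noise estimate uncontaminated by true alterations — and
computed on segment values, probe-weighted for the median. Thresholds:
gain/loss at m ± 2σ, amplification/deletion at m ± 4σ, strict inequalities.
σ = 0 collapses all thresholds and every call is Neutral (warned).

Gene states use 1-based inclusive interval overlap (any ≥ 1 bp counts).
Among overlapping segments the maximal-severity state wins
(Neutral < Gain/Loss < Amplification/Deletion); equal-severity sign
conflicts resolve to the segment with the larger |seg_mean|. The call
matrix is verified in the tests against a brute-force enumeration oracle.

Expression tails: per gene, a Gaussian MLE fit (mean, ddof = 0 variance)
across all samples of the cancer type; values strictly beyond
μ ± 1.6449σ are flagged under/over (5% tails). Joint event matrices
(Amplification ∧ over, Deletion ∧ under) are counted per gene over tumors
and ranked descending with lexicographic tie-break. Mutation ranking counts
distinct samples with at least one non-silent record; this frequency
ranking stands in for background-corrected mutation significance, which is
out of scope.

## Network and domains

Coarse domains come from case-insensitive substring matching of the three
shipped keyword lists (intracellular, membrane-receptor, extracellular)
against the gene's localization terms. Multi-domain hits resolve EC∧MR → EC
and MR∧IC → IC; EC∧IC without MR resolves to EC (extracellular annotation
is rarer and more specific; switchable). Unmatched genes are unannotated
and excluded from domain analyses. Fine domains are structural: EC genes
with/without an MR neighbour are SF/GM, IC genes ICRS/ICNRS.

Network construction: drop self-loops and duplicates, take the largest
connected component, remove edges outside {EC-EC, EC-MR, MR-IC, IC-IC},
then re-extract the largest component (prune-then-re-extract; the
alternative order is not distinguishable from the reported counts).
Sparsity is 2E/(N(N−1)).

Topology comparisons use one-tailed Mann–Whitney rank-sum tests. The
"paired" wording in the source for shortest-path comparisons is
contradictory — pairing is undefined between distance vectors of unequal
length — so the unpaired test is used, matching the degree analysis. Small
comparisons (≲ 20k group relabelings) are computed by exact enumeration of
the pooled rank splits, which is correct under ties; larger ones use the
tie-corrected normal approximation. Alteration-class genes missing from
the network are dropped (counted, warned), not imputed; classes with fewer
than 5 mapped genes yield missing p-values. Shortest paths are unweighted
BFS lengths, validated against a Floyd–Warshall oracle.

## Enrichment and meta-analysis

Domain enrichment is a one-tailed Fisher's exact test on
(in list / not) × (EC+MR / IC) against the annotated-network gene universe
(the whole-network background implied by the observed/expected barplots;
a pathway-restricted background is switchable). Directions per class:
DNAm classes and mutations test EC+MR excess (OR > 1), SCNA classes EC+MR
depletion (OR < 1). The expected count is list size × background EC+MR
fraction. "Equalized" mode truncates all class lists to the common minimum
length before testing. The odds ratio reported is the sample ratio ad/bc
(0/0 undefined → NaN, x/0 → ∞); degenerate margins force p = 1 so the
meta-analysis never silently skips a pathway.

Pathway-level tests restrict to pathway members with an EC or IC coarse
label (pure-MR members fall outside the 2-domain assignment). The
differential test rows are DNAm-altered (HyperM ∪ HypoM) vs SCNA-altered
(Amplification ∪ Deletion); the enrichment variant compares altered vs
unaltered pathway members. Genes in several pathways count in each
(standard GMT semantics). Per-pathway p-values are combined across cancer
types by Fisher's method (χ² with 2k df; missing types reduce k; p = 0
inputs are clamped to the smallest positive float with a warning). Raw
meta p-values are the primary output, matching the source's 0.05 cutoff;
BH-adjusted values are appended in a clearly labeled extension column. The
cumulative mode sums the per-type 2×2 tables before a single test. The
reverse-direction scan (IC excess of DNAm) is available through the
direction parameter but is not an output artifact.

A note on calibration: inclusive one-tailed exact Fisher p-values are
discrete and stochastically larger than uniform, so Fisher's combination of
them is conservative — under an exchangeable null the fraction of pathways
with meta p < 0.05 falls well below the nominal 5% at desk-scale counts.
The test is therefore valid (never anti-conservative) but not exact; the
planted-pathway recovery results rely only on validity plus power.

## Deregulation categories and enzyme co-expression

Categories per gene and cancer type: HyperM_F (significant
hypermethylation *and* significant underexpression at the driver
thresholds), HyperM_NF (hypermethylation without it), HypoM_F/HypoM_NF
mirrored, NC otherwise. Cross-type consistency: the statistic is the mean
over cancer-type pairs of the fraction of genes with identical categories;
the null permutes gene labels independently within each cancer type
(the simplest exchangeable null preserving per-type category frequencies —
the original statistic is not defined in the source); p = (1 + #{perm ≥
obs})/(n_perm + 1), with the 1/(n_perm+1) floor reported as "≤". Each
cancer type's permutation stream is keyed by its label, so the p-value is
invariant to the order types are supplied.

Enzyme correlation: Pearson r with two-sided p per (target, enzyme, cancer
type), tumors only. Label "positive" requires r > 0 with p < 0.05 in at
least half of the cancer types with data *and* no significant negative
type; "negative" mirrored; otherwise "none". "Significantly consistent" is
not quantified in the source; this
majority-with-no-significant-contradiction rule matches the described
coloring and is configurable. Zero-variance vectors are excluded from the
rule. Correlation p-values are raw and two-sided.

## Synthetic-data model

The generator emulates the statistical structure the analysis assumes, not
array physics: no probe-chemistry bias, purity/clonality, or read counts.

* **Interactome.** Preferential attachment: nodes arrive in order and
  attach `m` edges (default 3) with probability ∝ (degree+1)^power
  (default 1) among hierarchy-consistent partners. Nodes whose consistent
  partners have not arrived yet defer attachment and are wired in a final
  pass; label mixes admitting no consistent pair at all (e.g. all-MR) fall
  back to unrestricted attachment, producing exactly the prunable edges the
  pruning tests need. Coarse labels are drawn from the aggregated EC/MR/IC
  fractions of `domain_fractions`; the SF/GM and ICRS/ICNRS splits are
  derived from realized receptor contact, since they are structural
  properties, not free labels. Localization terms are drawn from
  vocabularies consistent with the keyword lists, so domain annotation
  round-trips exactly.
* **Planting.** The five alteration classes are pairwise disjoint draws,
  weighted by preferred coarse domain (default odds 3:1; DNAm classes
  toward EC/MR, SCNA classes toward IC) and optionally by degree
  (∝ degree+1 or its inverse). With `planted_pathway`, one EC-rich pathway
  is generated and HyperM planting concentrates on its EC members.
* **Methylation.** Per-probe group means (promoter baseline U(0.15, 0.45);
  HypoM baselines U(0.45, 0.75) to leave room for the −Δβ shift; body
  probes U(0.4, 0.8), identical in both groups) with logit-normal noise of
  sd 0.5 on the logit scale — bounded support with realistic dispersion.
  Tumor promoter means shift by ±Δβ (default 0.3); means are clipped to
  [0.01, 0.99] with a warning if an effect would leave the unit interval.
* **Expression.** Gaussian on the log2 scale (gene baselines N(8, 2),
  noise sd 1). DNAm-class tumors shift by ∓log₂FC (default 2) in all
  tumors (methylation is clonal); CN-class shifts apply only in carrier
  tumors (default 60% of tumors), coupling the per-sample joint events the
  Amplification/Deletion ranking counts. An optional latent tumor factor
  ties two designated "enzyme" genes positively and planted HyperM genes
  negatively (HypoM positively), for the co-expression analyses.
* **Copy number.** One linear pseudo-chromosome, genes tiled at 10 kb
  spacing (5 kb long, 1-based inclusive) — the simplest geometry
  exercising segment–gene overlap. Each tumor gets a mostly-neutral
  segmentation backbone (one segment per ~5 genes, ≥ 20, seg_mean
  N(0, 0.08)) plus one event segment per carried planted event covering
  the gene ± 2 kb with |seg_mean| ≥ `cn_shift` (default 1.0). The backbone
  dominates the segment count so the per-sample noise estimate is
  uncontaminated, as in real arrays where most of the genome is neutral.
* **Mutations.** Planted genes are mutated (missense) in
  ⌈`mutation_rate`·n_tumor⌉ distinct tumors (default rate 0.2); background
  calls arrive at rate 0.005 per gene-tumor, 30% silent.
* **Cohort sizes.** Defaults 50 normals + 50 tumors, 300 genes, one
  synthetic cancer type per call; multi-type analyses loop with per-type
  subseeds. Test and acceptance runs use 120–400 genes and 15–50 samples
  per group — sizes chosen so every planted effect is comfortably powered
  while whole-pipeline replicates stay cheap.

Fixed seeds reproduce every output byte-for-byte (sorted iteration
everywhere; one `numpy` generator per artifact). What passing tests show
about real data is limited: the generator has no probe-type bias, no
cell-type heterogeneity, no correlated gene modules beyond the planted
classes, and Gaussian expression noise; recovery rates on it are
upper bounds on real-data behavior.

## Pipeline conventions

`RunConfig` carries every threshold with its default and round-trips
through YAML losslessly. Each written table starts with provenance
comments: package version, a content hash of the analytic configuration
(output paths excluded) and the seed. Stages are pure functions of
(inputs, config, seed), so re-running any stage from written upstream
files is bit-reproducible; an explicit content-addressed cache layer was
considered and dropped as redundant under this determinism contract.
Errors abort with the stage name and the offending input. The CLI
(`methnet simulate|preprocess|call-dnam|call-scna|call-mut|network|enrich|
coexpr|run-all|meta`) is a thin wrapper over the library; the library
functions are the primary interface.

## Known limitations

* The BMIQ-style probe-type correction, interactome assembly from primary
  databases, hg19 coordinate construction and background-corrected
  mutation significance are out of scope; inputs arrive pre-reduced.
* Fisher-exact conservativeness on small tables (above) makes pathway
  meta p-values conservative at desk scale.
* The knn-imputation orientation, the EC∧IC precedence, the integrative
  statistic and the consistency-label rule are documented interpretations
  where the source under-specifies; each is isolated behind one switchable
  function or parameter.
* The degree comparison treats top-k lists as exchangeable gene sets;
  list-composition biases (e.g. CNV segments covering gene-dense regions)
  are not modeled by the generator.
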