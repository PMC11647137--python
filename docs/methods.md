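# Methods

## The score

For a sample with expression profile `x` over `N` genes, genes are ranked
within the sample (average ranks at ties; the highest expression gets rank
`N`). For a gene set `S` the enrichment score walks the genes in decreasing
rank order (ties broken by ascending symbol for determinism) and accumulates
the difference between the weighted in-set step function and the uniform
out-of-set step function:

    P_in(i)  = Σ_{g∈S, pos(g)≤i} R_g^α / Σ_{g∈S} R_g^α
    P_out(i) = |{g∉S, pos(g)≤i}| / (N − |S|)
    ES(S)    = Σ_i  P_in(i) − P_out(i)

with α = 0.25, the canonical ssGSEA exponent. Because only within-sample
ranks enter, ES is invariant to any strictly increasing per-sample transform
— library-size scaling, log transforms and TPM/FPKM conversions change
nothing. Scores for a collection of sets are normalized cohort-wide by
dividing by (max ES − min ES) over the whole score matrix; this puts all
signatures on one scale but makes each sample's score depend on its cohort
(the score is not computable for one sample alone).

The composite is

    IKCscore = ES(immune pattern) + ES(checkpoint set) − ES(keratin pattern)

with the three components normalized jointly (one ssGSEA call over the
3 × samples matrix) so their sum is on a single scale. The checkpoint set is
fixed: CD274, PDCD1LG2, CTLA4, PDCD1, LAG3, HAVCR2, TIGIT (the literature
alias PD-L1/PDL1 is mapped to CD274 by the shipped alias table). Samples are
dichotomized at a cutoff with `score > cutoff → high`; boundary samples go to
the low group.

## Derivation pipeline

Stages, in run order, with the defaults of the shipped preset:

1. **Signature screen.** ssGSEA-score every signature of a library over the
   cohort; two-sided Wilcoxon rank-sum test of responders (CR/PR) vs
   non-responders (SD/PD) per signature; keep the top 15 per direction among
   those with p < 0.05, ranked by ascending p (ties by |median difference|,
   then name).
2. **Gene pooling and screen.** Pool the member genes of the selected
   signatures (union, deduplicated) and keep every gene individually
   associated with response (rank-sum p < 0.05 on normalized expression).
3. **Differential expression.** Median-of-ratios (size-factor) normalization
   of the raw counts; per-gene rank-sum p and pseudocount fold change
   log2((mean_R + 1)/(mean_NR + 1)); candidates need p < 0.005 and
   |log2FC| > 1; top 35 per direction by p.
4. **Union, pseudogene filter, final screen.** Union of stages 2–3; genes
   whose biotype (user-supplied table, e.g. GENCODE-derived) contains
   "pseudogene" are removed; a final rank-sum screen keeps the top 30 per
   direction → the final panel.
5. **Pattern discovery.** log2(x+1)-transformed normalized expression of the
   panel genes is z-scored per gene (sample sd) and clustered with K-means
   (k = 5, Lloyd, k-means++, best of 25 restarts, seeded). Each cluster gets
   a response association score — the mean over member genes of
   (mean z in R − mean z in NR). The argmax cluster is labeled the immune
   pattern, the argmin the keratin pattern; an exact tie is an error (rerun
   with another seed or k) rather than a silent tie-break, and near-zero
   associations everywhere trigger a warning.

Raw p-values drive every "top k" ranking; BH-adjusted values are reported
alongside in every table. All selections are deterministic: p, then
|effect|, then lexicographic feature name.

### Design choices

- **Rank-sum DE instead of a negative-binomial GLM.** The DE stage is a
  deliberate simplification: size-factor normalization plus Wilcoxon tests
  and a pseudocount log2FC. It is robust, assumption-light and pluggable —
  an external NB test can be substituted by replacing
  `screening.differential_expression`. It does not model gene-wise
  dispersion and will be conservative for low-count genes.
- **Pattern labeling by response association.** Biological labeling of gene
  clusters (GO enrichment: antigen presentation vs keratin filament) is out
  of scope here; the labels are assigned by the property the composite score
  actually exploits — which cluster is most up in responders and which most
  up in non-responders. On data where the clusters have a biological
  identity, the two labelings coincide by construction of the score.
- **log2 before z-scoring.** K-means on linear-scale counts lets the skewed
  multiplicative count noise dominate Euclidean distances; log2(x+1) is the
  field-standard variance-compressing transform and precedes
  standardization.
- **Cohort-level ssGSEA normalization** (global ES range), matching the
  GSVA-style ssGSEA default.
- **Aliases and case.** All symbols are upper-cased at ingestion; matching
  is exact string equality after alias mapping. Duplicate gene rows are
  collapsed by mean.

## Evaluation statistics

- **ROC/AUC** by the rank (Mann–Whitney) formulation: AUC = U/(n₊·n₋), so
  tied scores count half and the AUC is invariant to monotone transforms.
- **Kaplan–Meier** product-limit curves (lifelines); censoring shrinks risk
  sets without steps.
- **Log-rank test** implemented directly (hypergeometric expectation and
  variance per event time, χ² with 1 df) because the cutoff search needs the
  standardized statistic (O−E)/√V at every candidate split; cross-checked
  against lifelines in the test suite.
- **Univariate Cox** via lifelines with Efron tie handling and Wald 95% CI,
  fitted to |Δβ| < 1e-9. Monotone likelihood (perfect separation) is raised
  as an error by the primitive and reported as a flag
  (`cox_flag: monotone_likelihood`) by the cohort-level report.
- **Optimal cutoff**: scan the midpoints of consecutive sorted unique
  scores, keep splits leaving both groups ≥ minprop·n (minprop = 0.1),
  return the cutoff maximizing |standardized log-rank|; ties go to the lower
  cutoff. The p-value at the selected cutoff is *not* corrected for maximal
  selection and is flagged as exploratory.
- **Comparator bins**: PD-L1 TPS level 0 (<1%), 1 (1–49%), 2 (≥50%) and
  binary positive (≥1%); TMB high iff ≥ 10 mut/Mb (the boundary value 10 is
  classed high, following the label convention).

## Synthetic cohorts

The generator emulates an advanced-NSCLC ICB cohort at the level of
statistical structure, with every quantity reproducible from one seed:

- **Design.** 120 patients, 40% responders (responders mostly PR with
  occasional CR, non-responders SD-dominant); 2,000 genes with baseline
  abundance log2-uniform on [2, 10]; negative-binomial counts with
  var = μ + 0.2 μ².
- **Programs.** A 60-gene immune program shifted +1.5 log2 units in
  responders and a 60-gene keratin program shifted +1.5 in non-responders.
  Per-sample program activity carries N(0, 0.9²) heterogeneity — patients
  differ in how inflamed or keratinized their tumor is beyond the R/NR
  shift — which is what makes program genes co-expressed. Each program has a
  tightly co-regulated, well-expressed core (42% of genes, baseline in
  [5, 10] log2, loading 1.0 on the activity) and a loosely coupled periphery
  (loading 0.15, dispersion ×10): real transcriptional programs are not
  homogeneous blocks, and this core/periphery structure is what gives the
  final panel distinct tight and diffuse gene groups for k = 5 clustering to
  resolve. The 7 checkpoint genes are co-regulated with the immune program
  (coupling 0.6 plus N(0, 0.3²) own noise).
- **Outcomes.** PFS is exponential with hazard 0.05·exp(−1.0·(true score −
  mean)) per month, so high scores mean longer PFS; 30% of patients are
  censored at a uniform fraction of their event time (the censoring
  indicator is Bernoulli, making the censoring fraction an exactly binomial
  quantity). PD-L1 TPS is a noisy logistic transform of checkpoint activity;
  TMB is gamma-distributed independent of the score (so the observed
  score–TMB non-correlation is a designed, testable property); tumor purity
  rises with keratin activity.
- **Gene architecture vs patients.** Which genes belong to which program
  (and their baselines) is drawn from a separate architecture seed, fixed by
  default, while patients are drawn from the cohort seed — so two cohorts
  with different seeds share gene roles and a signature derived on one
  transfers to the other, as between a discovery and a validation cohort.
- **Signature library.** 100 synthetic sets of 10–50 genes standing in for a
  published signature compendium; 40 overlap a planted program in ≥50% of
  their members (alternating immune/keratin), the rest draw from null genes.

**What passing tests do and do not show.** The generator reproduces the
features the pipeline relies on — co-expressed response-associated programs,
overdispersed counts, informative censored survival, weak comparators. It
does not model library-size artifacts, GC bias, batch effects, cross-platform
differences or correlated null genes; performance numbers on it (AUC ≈ 0.93,
recovery ≥ 83%) characterize the implementation under its assumptions, not
expected clinical performance.

## Numerical conventions and degenerate inputs

z-scores use the sample standard deviation (ddof = 1); constant genes are
dropped with a warning before clustering. Rank-sum tests are exact when both
groups have ≤ 8 observations and no ties, otherwise normally approximated
with tie and continuity corrections. A gene set absent from a matrix is an
error if the overlap is empty and a warning (members dropped) otherwise; a
set covering every matrix gene is an error (the out-of-set step function is
undefined). Size-factor estimation requires at least one gene with all
positive counts and rejects all-zero samples. The acceptance script derives
all sub-seeds from its `--seed` argument modulo 2³¹.

## Problem sizes

The shipped analyses run at the generator's native scale: 120-patient
cohorts, 2,000 genes, 100 signatures; engine oracles use 200 random
instances of ≤ 25 genes; calibration uses 2,000 log-rank null simulations
and 200 Cox fits at n = 300. The complete test suite runs in about a minute;
the acceptance script in about twenty seconds.
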