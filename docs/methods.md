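# Methods

## Overview

`crdcnet` implements an integrative pipeline for finding chromosomal-
instability (CIN)–related dysregulated competing-endogenous-RNA (ceRNA)
modules with prognostic value in a tumor cohort:

1. **Normalization.** FPKM is renormalized per sample to TPM
   (columns sum to 10^6), then log2(x+1)-transformed; genes with more than
   30 % missing (NA) values are removed. Zeros in a TPM matrix are
   observed measurements, not missing values. lncRNAs are the transcripts
   of the seven non-coding biotypes (processed_transcript, lincRNA,
   3prime_overlapping_ncrna, antisense, non_coding, sense_intronic,
   sense_overlapping) longer than 200 nt; mRNAs are protein_coding.
2. **CIN scoring.** A sample's CIN score is the sum of TPM over a CIN
   signature gene set (CIN70 in real data). Patients are dichotomized at
   the StepMiner split: scores are sorted ascending and the interior split
   t maximizing SNR(t) = Σ(fit−μ)² / Σ(fit−xᵢ)² is chosen, where fit is
   the two-level step function with group means μ₁, μ₂. The sorted value
   at position t is the threshold; scores ≤ threshold are Low.
3. **CeRNA identification** (per CIN stratum, restricted to the DEG
   universe): an mRNA–lncRNA pair qualifies when it shares significantly
   many upstream miRNA regulators (upper-tail hypergeometric
   p = P(X ≥ r) with population N = all miRNAs in the interaction tables,
   K and M the per-gene regulator counts; BH-FDR < 0.05 across all
   candidate pairs) and is significantly co-expressed (Pearson r > 0.1,
   BH-FDR of the correlation p < 0.05, two-sided t with n−2 df).
4. **Double-weighted network.** Edges are the union of pairs qualifying
   in either stratum; the stratum where a pair failed contributes PCC 0.
   Edge weight E = Φ⁻¹(1 − p₂) where p₂ is the two-sided significance of
   z = |F(r_high) − F(r_low)| / √(1/(n_high−3) + 1/(n_low−3)),
   F = atanh. Node weight N = Φ⁻¹(1 − p) with p the gene's univariate Cox
   significance for disease-specific survival among untreated patients.
   Pairs are typed *gain* (r_high > r_low) or *loss* (r_high < r_low).
5. **Dense modules.** Module score = λ·ΣE/n_E + (1−λ)·ΣN/n_N
   (λ = 0.44). Every node seeds a greedy growth: repeatedly add the
   neighbor (shortest-path distance ≤ d = 1) giving the highest new
   score, accepted only while increment > r·previous score (r = 0.1).
   The top 10 % of modules by score (ceiling; ties at the cutoff
   retained) enter a permutation filter: a module survives when its
   multivariate Cox likelihood-ratio p beats the p-values of equally
   sized random gene sets drawn from the network background
   (random_p = fraction of n_perm = 10 000 random p strictly below the
   observed; keep random_p < 0.01). Survivors are merged via shared genes
   into the CRDC gene set.
6. **Risk score.** Each CRDC gene's univariate Cox log hazard ratio
   (natural log; DSS, untreated patients) becomes its coefficient;
   the per-sample score is Σᵢ expressionᵢ·log(HRᵢ) on log2TPM.
   Patients are split High/Low by StepMiner and compared by
   Kaplan–Meier/log-rank; discrimination is summarized by ROC AUC.
7. **Immune metrics** (closed-form, per sample): cytolytic activity
   CYT = √(GZMA·PRF1) in TPM; tumor mutation burden
   TMB = non-synonymous CDS mutations / total CDSs × 10⁶; tumor purity
   = cos(0.6049872018 + 0.0001467884 · ESTIMATE score).

## Design choices where the method was open

* **Edge-weight denominator.** The default uses the statistically
  standard Fisher-comparison standard error √(1/(n−3) + 1/(n−3)).
  A `variant="printed"` flag evaluates 1/(n+3) + 1/(n+3) with no square
  root instead, for audits against descriptions that use that form; it is
  a monotone rescaling of |z| at fixed stratum sizes, so pair ranking
  within a network is unaffected, but the null calibration of the
  internal p-value holds only for the default.
* **Probability clamping.** Inner probabilities are clamped to
  [1e−16, 1−1e−16] so E and N stay finite; the quantile is evaluated in
  the accurate tail (via erf for the complement) so the clamp bounds are
  exact: max |E| = |Φ⁻¹(1e−16)| ≈ 8.222.
* **Correlation-FDR family.** BH for the co-expression p-values is
  applied to the pairs that already passed the hypergeometric filter
  (sequential filtering). Correcting over the full mRNA×lncRNA candidate
  family (~10⁵ pairs here) instead would destroy power for any
  moderate correlation and makes the weaker stratum of every truly
  dysregulated pair undetectable; the sequential family matches the
  two-step description of the screen.
* **Hypergeometric background.** The miRNA universe is the union of all
  miRNAs appearing in the supplied miRNA–mRNA and miRNA–lncRNA tables —
  reproducible from the inputs alone.
* **Differential expression.** The DEG universe is produced by a
  pluggable two-group stage; the default is a two-sided Mann–Whitney test
  on log2TPM with BH correction and the thresholds |log2FC| > 1,
  FDR < 0.01 (log2FC = difference of group means in log2TPM). A
  count-model backend can be substituted; downstream stages consume only
  the resulting gene universe.
* **StepMiner details.** SNR is evaluated at every rank (not unique
  values); a perfect step (zero residual) scores +∞ and wins; all ties
  resolve to the smallest t; samples exactly at the threshold are Low.
  Candidate splits keep both groups non-empty.
* **Module statistics.** The module's observed significance is the
  likelihood-ratio p of the joint Cox fit (Wald available by config).
  Equal-sized modules share one null distribution of random-set p-values
  (the null depends only on module size), which cuts the permutation cost
  without changing the statistic. Random draws are uniform over the
  network's genes, not stratified by biotype. The growth-acceptance rule
  is applied verbatim even when the previous score is negative.
* **Cox machinery.** All proportional-hazards fits use an internal
  Newton–Raphson partial-likelihood solver with Efron tie handling,
  vectorized so that the permutation filter's ~10⁴–10⁵ fits run in
  seconds; it is validated against lifelines (tied and untied data,
  agreement ≲ 1e−4, their convergence tolerance) and against brute-force
  partial-likelihood maximization in the test suite. Genes whose fit does
  not converge are dropped from the risk model with a warning. log(HR)
  is the natural logarithm. Expression is not standardized before the
  risk sum.
* **Top-10 % rounding.** ceil(0.10·count) modules are kept and ties at
  the cutoff score are all retained.

## The synthetic cohort

The generator (`crdcnet.simulate`) produces data with exactly the
structure the stages assume, so each has a recoverable planted answer.
Defaults define the study conditions; all values are set once.

| parameter | default | meaning |
|---|---|---|
| n_genes / n_lncrnas / n_mirnas | 1000 / 120 / 150 | universe sizes |
| n_tumor (CIN-High + CIN-Low) | 600 (300 + 300) | patients |
| n_adjacent | 60 | adjacent-normal samples |
| n_planted_gain / n_planted_loss | 25 / 25 | dysregulated pairs |
| r_high/r_low (gain) | 0.6 / 0.2 | stratum PCC targets (Δr = 0.4) |
| r_high/r_low (loss) | 0.2 / 0.6 | mirror of gain |
| module (mRNAs × lncRNAs) | 3 × 3, gain-type | planted connected module |
| n_cin_like_genes / cin_shift | 70 / 1.0 log2 | CIN signature and its tumor offset |
| cin_shift_within | 1.0 log2 | CIN-High vs CIN-Low offset |
| planted_de_shift | 2.0 log2 | tumor offset of planted ceRNA genes |
| n_prognostic / beta_range | 6 / (0.7, 0.7) | planted log-HRs (module genes first) |
| censor_rate / treatment_rate | 0.30 / 0.30 | censoring and treatment-flag rates |

Gene baselines are drawn with log2 means uniform in [2, 10] and unit
noise SD (log-normal TPM skew after exponentiation). Planted pairs and
the planted module are Gaussian copulas in log2 space (equicorrelated
within the module), so target PCCs survive the monotone TPM and
log2(x+1) transforms to good approximation. CIN-like genes get the tumor
and CIN-High mean offsets so a CIN-score StepMiner split can recover the
strata; planted ceRNA genes get a tumor offset so they survive the
DEG-universe restriction, mirroring how the real analysis screens ceRNA
candidates from differentially expressed genes. Survival times are
exponential proportional-hazards draws on the standardized log2
expression of the prognostic genes with baseline median 1000 days;
censoring is uniform on (0, c) with c calibrated by root-finding so the
expected censored fraction equals `censor_rate`; the treatment flag is
independent of outcome, making the untreated subset an unbiased
subsample. The planted-pair density (50 pairs → ≈106 network nodes of
1120 genes, ~9 %) emulates the density of real dysregulated ceRNA
networks, which cover a few percent of the expressed gene universe.

One root seed drives per-stage child streams keyed by stage name, so
outputs are byte-identical across reruns and insensitive to stage
reordering.

**What the generator does not emulate:** read-count noise (negative
binomial per library), batch effects, copy-number structure, realistic
miRNA expression, or correlated censoring. Passing tests demonstrate
that the machinery recovers the structure it assumes; they do not
certify performance on real cohorts, where effect sizes are smaller and
confounding is present.

## Numerical and scale choices

Verification problem sizes were chosen to make each property measurable
with margin: oracle equivalences run exhaustively (all hypergeometric
configurations with universe ≤ 12; every interior StepMiner split at
n ≤ 200; all connected subgraphs of ≤ 8-node networks), calibration
nulls use 1000 simulated pairs / 50 replicate module sets at
n_perm = 1000, Cox recovery uses ~500 cohorts of n = 500, and the
end-to-end recovery runs the full default cohort over 10 seeds.

## Known limitations

* The greedy module search is a hill climb: it provably cannot always
  reach the globally best connected subgraph (reaching it can require
  crossing a score dip the acceptance rule forbids). On random ≤8-node
  networks with standard-normal weights it matches the exhaustive
  optimum for roughly 80 % of seeds and is never better; the remainder
  are local optima. This is a property of the search rule itself, not
  of its implementation, which is trace-verified (every accepted
  addition beats the growth threshold) and oracle-checked on cases
  without dips.
* With saturated weights, greedy modules plateau at two nodes (adding a
  third equal-weight node leaves the mean score unchanged, failing the
  relative-increment rule); larger signatures emerge through the merge
  step, as small overlapping modules coalesce into one subnetwork.
* The permutation filter's background contains the planted signal genes
  (as it does in real data); at very small network sizes this makes
  random_p conservative.
* TMB divides by the number of CDSs (as defined), not by megabases of
  sequenced territory; values are not comparable to conventional
  mutations/Mb.
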