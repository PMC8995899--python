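# crdcnet

Chromosomal-instability-related dysregulated ceRNA networks: from
expression matrices and miRNA–target interaction tables to a
double-weighted dysregulated ceRNA network, dense prognostic modules, and
a gene-signature risk score.

## The problem

Long non-coding RNAs can regulate mRNAs indirectly by competing for
shared microRNAs (the ceRNA mechanism), and the strength of this
co-regulation can differ between tumors with high and low chromosomal
instability (CIN). `crdcnet` is for computational biologists who want to
(i) quantify CIN per sample from a signature gene set, (ii) find
mRNA–lncRNA ceRNA pairs whose co-expression is *gained* or *lost* in
CIN-High versus CIN-Low patients, (iii) mine the resulting network for
dense modules that are also prognostic, and (iv) turn the merged module
genes into a per-patient risk score.

## The model

For an mRNA–lncRNA pair, shared upstream regulation is tested with the
upper-tail hypergeometric probability P(X ≥ r) (r shared miRNAs, M and K
per-gene regulator counts, N background miRNAs), and co-expression with
Pearson correlation (r > 0.1, BH-FDR < 0.05) within each CIN stratum.
The network is double-weighted:

* edge weight  `E = Φ⁻¹(1 − p₂)` where p₂ is the two-sided significance
  of `z = |atanh(r_high) − atanh(r_low)| / √(1/(n_high−3) + 1/(n_low−3))`
  (Fisher z comparison of the stratum correlations);
* node weight  `N = Φ⁻¹(1 − p)` with p from a univariate Cox model of
  disease-specific survival on untreated patients.

Modules score `λ·ΣE/n_E + (1−λ)·ΣN/n_N` (λ = 0.44) and grow greedily
from every seed node (neighbor distance d = 1, relative increment
r = 0.1). The top 10 % by score are kept if their multivariate Cox p
beats 10,000 equally sized random gene sets (random p < 0.01), and the
survivors are merged via shared genes into the CRDC signature. Each
signature gene's univariate Cox log(HR) weights the per-sample risk
score `Σᵢ expressionᵢ · log(HRᵢ)`; patients are dichotomized by the
StepMiner maximum signal-to-noise split and compared by log-rank.

A synthetic-cohort generator plants all of this structure — gain/loss
correlated pairs, a connected prognostic module, shared-regulator
overlap, proportional-hazards survival — so every stage has a
recoverable ground truth. See `docs/methods.md` for the full model,
parameter table, and design choices.

## Worked example

Run the whole pipeline on a synthetic cohort (1000 mRNAs, 120 lncRNAs,
300 CIN-High + 300 CIN-Low tumors, 60 adjacent samples, a planted
3 mRNA × 3 lncRNA prognostic module with Δr = 0.4 and log-HR 0.7):

```python
from crdcnet import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(seed=1), n_perm=1000, seed=1)
res = run_pipeline(cfg, "runs/demo")
print(res.crdc_genes)
print(res.evaluation)
```

prints

```
['G00050', 'G00051', 'G00052', 'LNC0050', 'LNC0051', 'LNC0052']
{'logrank_chi2': 447.757..., 'logrank_p': 2.22e-99, 'risk_threshold': 41.87...,
 'n_high': 347, 'n_low': 253, 'tumor_vs_adjacent_auc': 0.9545}
```

The six recovered CRDC genes are exactly the planted module. The network
stage found 106 nodes / 59 edges (34 gain, 25 loss), the greedy search
produced 106 seeded modules of which 12 passed the top-10 % filter and 6
survived the permutation filter; the merged signature's risk score
splits the 600 tumors into 347 high- / 253 low-risk patients whose
disease-specific survival separates at log-rank p ≈ 2×10⁻⁹⁹, and the
score discriminates tumor from adjacent samples with AUC 0.954. The
fitted per-gene hazard ratios (e.g. G00050: HR 2.63, 95 % CI 2.30–3.00)
recover the planted prognostic effect.

The same run is available from the shell:

```sh
crdcnet run-all --out runs/demo --seed 1 --n-perm 1000
```

plus per-stage subcommands (`simulate`, `preprocess`, `de`, `cin`,
`network`, `modules`, `score`, `evaluate`).

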