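# chemoscore

A tested, reusable implementation of a 4-chemokine expression biomarker
pipeline for predicting T cell-inflammation and immune-checkpoint-inhibitor
(ICI) treatment benefit across solid tumor types.

## The problem and the score

Tumor mutational burden (TMB ≥ 10 mutations/Mb) is the tumor-agnostic
biomarker most often used to select patients for ICI therapy, but many
T cell-inflamed tumors are TMB-low. The **c-Score** summarizes the
chemokine milieu that recruits effector immune cells into the tumor:

```
c-Score(sample) = mean of log2(TPM + 0.001) over {CCL4, CCL5, CXCL9, CXCL10}
```

Samples are stratified by global cohort quartiles of the c-Score:

- **c-Score^hi** — score ≥ Q3,
- **c-Score^lo** — score ≤ Q1,
- **c-Score^med** — otherwise,

with Q1/Q3 either the shipped fixed pan-cancer defaults (1.940425 /
4.835088) or recomputed cohort-relative (linear interpolation between order
statistics). For outcome analyses, lo and med are pooled into the
**lo+med** reference group. Around the score, the package provides:

- **TMB** from MAF-style mutation tables (non-silent counts / 35.8 Mb by
  default, TMB^hi at ≥ 10 mut/Mb inclusive), protein-truncating
  classification, DNA-repair-pathway mutation rates and KRAS status;
- **MSI/HRD subtyping** from precomputed MANTIS (> 0.4), HRDScore (≥ 46 in
  BRCA/OV, ≥ 27 elsewhere) and MSIsensor (> 0.2) values, with MSI taking
  precedence over HRD, and a per-tumor-type "TMB-associated" classification
  (Wilcoxon rank-sum + Benjamini–Hochberg FDR, direction-aware);
- **ssGSEA immune-geneset enrichment** (rank-weighted running-sum statistic,
  `tau = 0.25`, cohort-range normalization, signature chemokines removed
  from genesets first) and an arbitrary-unit (AU) translation of group
  medians that pins the lo+med group at AU = 1;
- **outcome analysis**: durable clinical benefit (DCB: > 183 days of
  treatment without progression), per-group response rates, Kaplan–Meier /
  log-rank comparisons of time to progression (TTP) and overall survival
  (OS), Cox proportional-hazards models with Efron tie handling, and
  covariate-controlled linear comparisons;
- a **seeded synthetic cohort generator** that emulates the multi-tumor-type
  structure these analyses assume (latent inflammation factor, cold types,
  MSI/HRD minorities with inflated mutation loads, planted hazard ratios),
  so the whole pipeline is testable end to end without controlled-access
  data.

## Worked example

```python
from chemoscore import *
from chemoscore.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(n_tumor_types=8, samples_per_type=50,
                          n_cold_types=2, n_tmb_associated_types=3,
                          tmb_base_mean=30.0, seed=11)
expression, maf, clinical = simulate_cohort(config)
clinical = clinical.set_index("sample_id")

scores = compute_cscore(expression)
thresholds = derive_thresholds(scores)
strat = stratify(scores, thresholds, tumor_types=clinical["tumor_type"])
pooled = pool_groups(strat["group"])

tmb = compute_tmb(maf, samples=list(expression.columns))
enr = enrichment_table(filter_expressed_genes(expression),
                       prepare_genesets(DEFAULT_GENESETS))
au = au_transform(enr, pooled)
km = km_logrank(clinical["ttp_days"], clinical["ttp_event"], pooled)
```

This prints (seed 11):

```
thresholds: q1=1.248 q3=4.362
group sizes: {'med': 166, 'hi': 83, 'lo': 83}
included tumor types: ['BRCA', 'COAD', 'LUAD', 'OV', 'PAAD', 'STAD']
TMB-associated types: ['BRCA', 'LUAD', 'STAD']
           geneset  group  median_score       au
cytolytic_activity     hi      0.391545 1.228936
cytolytic_activity lo+med      0.162609 1.000000
median TTP (days): hi=134 lo+med=83, log-rank P=0.0106
Cox HR (hi vs lo+med) = 0.65 [0.47-0.91], P=0.0112
```

Reading it: the cohort splits 25/50/25% by quartiles; the two cold tumor
types fail the ≥ 5-patients-per-group filter; exactly the three types
planted with elevated TMB in the hi group are flagged TMB-associated; the
cytolytic-activity geneset is enriched in hi tumors (AU 1.23 vs the
reference 1.00); and the hi group shows the planted survival benefit (true
hazard ratio 0.5 inside the Wald 95% CI).

A thin CLI mirrors the library:

```bash
chemoscore simulate --out-dir cohort --seed 11 --n-tumor-types 8 --samples-per-type 50
chemoscore stratify --expression cohort/expression.tsv --log-transformed \
    --thresholds cohort --clinical cohort/clinical.tsv --out strat.tsv
chemoscore tmb --maf cohort/mutations.maf --out tmb.tsv
chemoscore survive --clinical cohort/clinical.tsv --stratified strat.tsv \
    --endpoint ttp --out cox.tsv
```

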