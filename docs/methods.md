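# Methods

## Score and stratification

The c-Score is the per-sample arithmetic mean of the stored
log2(TPM + 0.001) values of *CCL4*, *CCL5*, *CXCL9* and *CXCL10*. The
pseudo-count of 0.001 floors zero TPM at log2(0.001) ≈ −9.9658; all
expression handling in the package happens on this scale.

Quartile thresholds use linear interpolation between order statistics at
position (n − 1)·p + 1 (numpy's default quantile). This convention is the
one under which 6987 distinct scores split exactly 1747 / 3493 / 1747:
Q3 falls between ranks 5240 and 5241, so ranks 5241–6987 (1747 samples) sit
at or above it, and symmetrically for Q1. Stratification tests `hi`
(score ≥ Q3) before `lo` (score ≤ Q1); in the degenerate case Q1 = Q3 a
boundary score is therefore `hi`, making the assignment total. The fixed
pan-cancer thresholds (Q1 = 1.940425, Q3 = 4.835088) ship as named defaults;
cohort-relative thresholds are an explicit opt-in so that external cohorts
can be scored either against the discovery thresholds or against themselves.

Tumor types enter group-comparison analyses only when each of hi/med/lo has
at least five patients. Pooling collapses med and lo into the `lo+med`
reference.

## Mutation metrics

TMB is the number of counted mutation records divided by the exome capture
size (default 35.8 Mb). The default counted set is the non-silent
convention: every standard MAF class except Silent, UTR/flank, intron, IGR,
RNA and targeted-region records. The set is configuration, not a claim of
bit-equivalence with any particular upstream caller. TMB^hi is inclusive at
10 mutations/Mb. Protein-truncating means exactly: Frame_Shift_Del,
Frame_Shift_Ins, Nonsense_Mutation, Splice_Site, Translation_Start_Site,
Nonstop_Mutation; unknown classification strings never count and warn once
per distinct string. Pathway rates are reported two ways per group: mutation
records per patient (count rate) and the fraction of patients with at least
one hit (patient fraction), optionally restricted to truncating records.
KRAS status is mutated iff the sample has ≥ 1 non-silent KRAS record.

## Genomic subtyping

MANTIS > 0.4 and MSIsensor > 0.2 are strict; HRDScore ≥ 46 (BRCA/OV) or
≥ 27 (rest) is inclusive, and the two strata's third quartiles can be
recomputed from data with the same interpolation convention as the c-Score
quartiles. Missing MANTIS/HRD values classify as low everywhere — applying
this rule globally (rather than only in mutation-status analyses) keeps
subtype assignment total; the imputed-low counts are visible in the
classifier inputs. Precedence is MSI over HRD over the pooled c-Score label,
so every sample receives exactly one of MANTIS^hi, HRDScore^hi, c-Score^hi,
c-Score^lo+med.

A tumor type is "TMB-associated" when the two-sided Wilcoxon rank-sum
comparison of TMB between hi and lo+med survives Benjamini–Hochberg FDR at
α = 0.05 across types *and* the hi-group median exceeds the lo+med median.
The direction requirement makes the label one-sided without changing the
test. Types with fewer than two samples in either pooled group are
unassociated with a warning. r×2 contingency comparisons use Pearson
chi-squared without continuity correction; 2×2 tables use the two-sided
Fisher exact test.

## Enrichment and arbitrary units

Genes with zero TPM in strictly more than 50% of samples are removed before
enrichment (a gene zero in exactly half is retained). The four signature
chemokines are removed from every geneset first; a geneset emptied by the
removal is dropped with a warning.

The single-sample enrichment score is the rank-weighted running-sum
statistic: within each sample, genes get ranks 1..G by expression (highest
expression = rank G; ties averaged); genes are walked in order of decreasing
expression, in-set genes advance a weighted ECDF with weight rank^tau
(tau = 0.25), out-of-set genes advance a uniform ECDF, and the score is the
sum of the ECDF differences over all positions. With normalization enabled,
all scores in a run are divided by the (max − min) range over the whole
geneset × sample table (a degenerate zero range leaves scores untouched).
Walk order among tied values is stable in input order; since tied in-set
genes carry equal average-rank weights, the statistic is unaffected. The
vectorized implementation is checked against a term-by-term brute-force
oracle to 1e−10 on random fixtures, and is invariant to strictly monotone
per-sample transforms by construction.

The AU translation maps the group medians of each geneset's scores to
AU = 1 + (median_group − median_ref) with the lo+med group as reference.
This is algebraically median_group + 1 − median_ref but evaluated so the
reference group is *exactly* 1.0 in floating point, and between-group median
differences are preserved exactly. The reference-group median — not
necessarily the global minimum — is what is pinned at 1; display is the only
purpose, and all statistics are computed on untransformed scores.

## Outcome analysis

Survival times are days throughout. DCB requires strictly more than 183
days (six months) of treatment without progression inside that window.
Kaplan–Meier medians are the first time the survival estimate drops to
≤ 0.5; a curve that never does is reported not-reached (NaN) and excluded
from median comparisons. Log-rank tests compare two or k groups. Cox models
are partial-likelihood fits with Efron tie handling (lifelines, Newton
convergence tightened to 1e−11 so small-sample fits agree with a direct
1-D partial-likelihood maximization to 1e−6); per-term P values are Wald,
with the model-level likelihood-ratio P also reported. When tumor type is a
covariate, only types with at least three patients enter the model.
Covariate-controlled group comparisons use OLS on a group indicator plus
one-hot covariates (binary responses included, matching the linear-model
convention; a logistic variant is a natural extension, not implemented).
Group comparisons of continuous values are two-sided Wilcoxon rank-sum;
multiplicity is always Benjamini–Hochberg.

## Synthetic cohort generator

The generator's defaults are the study conditions the analyses assume, not
tuning knobs:

| parameter | default | rationale |
|---|---|---|
| n_tumor_types / samples_per_type | 31 / 225 | ≈ 7000-patient pan-cancer cohort |
| n_cold_types | 6 | low-inflammation entities excluded by the ≥5-per-group filter |
| cold_type_size_divisor | 3 | cold entities are also the rarest cohorts in real data |
| inflammation_effect | 2.0 log2/unit | strong chemokine–immune co-expression |
| immune_loading | 0.8 | immune genesets track the factor slightly less than the chemokines |
| type_effect_sd | 0.3 (latent units) | between-type spread small enough that every warm type keeps ≥5 samples per group under global quartiles |
| msi_fraction / hrd_fraction | 0.03 / 0.24 | minority MSI, larger HRD subpopulation |
| tmb_base_mean / tmb_msi_multiplier | 100 / 10 | overdispersed (NB, dispersion 5) loads; MSI strongly inflated |
| tmb_association_multiplier | 3 (8 types) | planted hi-group TMB shift in the associated types |
| hazard_ratio_hi | 0.5 | planted treatment benefit of the hi group |
| ttp/os reference medians | 72 / 196 days | reference-group exponential scales |
| dcb_prob_by_group | 0.36 / 0.16 / 0.0 | planted response rates |
| censoring_rate | 0.3 | independent exponential censoring of the reference group |

Expression is log-normal on the TPM scale: gene baseline + loading ×
(inflammation factor + MSI/HRD boosts) + Gaussian noise, floored at
log2(0.001); a slice of background genes is zero-inflated so the expressed-
gene filter has work to do. The latent factor is standard normal around a
type mean; cold types sit 4 latent units below, so they contribute
essentially no hi samples. The planted survival grouping is the
cohort-relative quartile stratification of the *realized* c-Score, assigned
before hazards are drawn: downstream stratification therefore recovers the
planted groups exactly, and the hazard-ratio recovery checks measure
estimator coverage rather than label noise. Event times are exponential
with group-specific hazards and independent exponential censoring, giving a
closed-form planted hazard ratio. Mutation counts are negative binomial
with per-type lognormal mean multipliers; variant classes are drawn from a
fixed categorical over standard MAF classes; KRAS mutations are planted at
per-type prevalences (0.73 in PAAD down to 0 in MESO). MANTIS, HRDScore and
MSIsensor values are drawn from ranges consistent with planted MSI/HRD
membership (with a 2% missing fraction), so classifier thresholds recover
membership exactly on non-missing values.

What the generator does *not* emulate: copy-number and subclonal structure,
read-level noise, correlated geneset co-membership beyond the single latent
factor, non-proportional hazards, informative censoring, and the heavy
right-tail heterogeneity of real per-type sample sizes. Passing tests
therefore demonstrate correctness of the pipeline's arithmetic, decision
rules and statistical procedures under the planted model — not clinical
validity on real cohorts, and not reproduction of numbers that require
controlled-access discovery data.

## Problem sizes used in checks

The end-to-end checks run at deliberately modest scale: the quartile-count
check uses 6987 scores; hazard-ratio recovery uses 100 replicates of a
500-sample cohort (5 types × 100); TMB-association recovery uses the full
default cohort (25 warm types × 225 + 6 cold × 75); oracle comparisons use
200 random ssGSEA fixtures (≤ 20 genes × ≤ 5 samples), all 2×2 Fisher
tables with total n ≤ 30, BH vectors up to length 6, and rank-sum groups up
to 8 + 8. These sizes were chosen so the whole suite runs in well under a
minute per check while leaving the statistical conclusions unambiguous.

## Known limitations

- The ssGSEA statistic is the single-sample rank-weighted ECDF method only;
  the kernel-density GSVA variant is out of scope.
- Cox per-term P values are Wald rather than per-term score tests; the
  model-level likelihood-ratio test is reported alongside.
- The clinical reader accepts day offsets (preferred) or pre-computed
  durations; calendar-date arithmetic is the caller's responsibility.
- Missing expression cells are rejected rather than imputed.
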