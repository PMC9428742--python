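# Methods

## Scope and data model

The package analyses a nulliparous pregnancy cohort in which each
participant carries clinical covariates (age, BMI, waist, family history
of diabetes, PCOS, hypertension), a weekly physical-activity total in
MET·min/wk, a raw-scale polygenic risk score (PRS), and a binary
gestational-diabetes (GD) outcome. Two data sources are supported:
individual-level files (phenotype CSV, genotype VCF/TSV, weights TSV,
activity CSV) and published contingency counts, which `from_counts`
expands into individual-level rows so that resampling and regression run
identically on both.

## Case definition

GD is determined from glucose tolerance tests with inclusive ("at least")
mg/dL thresholds: 100-g 3-h fasting test, ≥2 abnormal of (95, 180, 155,
140); 75-g 2-h fasting test, ≥1 abnormal of (92, 180, 153); 50-g
non-fasting screen, ≥200, considered only when no fasting test exists.
Clinical diagnosis is a fallback used only when no GTT data are present;
when both exist, the GTT result wins. When a participant carries both
fasting protocols each is applied independently and GD is called if either
qualifies — the precedence between protocols is not defined by any
guideline we follow, so the disjunction is the least-assuming choice.
Comparisons are made in mg/dL throughout; a ×0.0555 helper converts to
mmol/L for display only.

The eligibility cascade removes, in order: participants missing all
covariates, prediabetes, pre-pregnancy diabetes, ancestry-ineligible
(an opaque caller-supplied flag — ancestry inference itself is out of
scope), no GD testing and no clinical diagnosis, missing/invalid METs,
missing PRS. The filter is idempotent and emits an ordered
`{step, n_removed}` report whose counts sum to the number excluded.

## Genotype QC and PRS

Per-variant missingness, minor-allele frequency (MAF) and the
Hardy–Weinberg exact-test p-value are always recomputed from the calls.
Defaults: drop variants with missingness > 0.02, MAF < 0.01, or HWE
p < 1e-6; drop samples with call rate < 0.98 or |F_het| > 0.2, where
F_het = 1 − observed/expected heterozygosity with the expectation
Σ 2p(1−p) over the variants the sample is typed at. The HWE test is the
standard exact test on hard calls (plain p, not mid-p), implemented with
the conditional-distribution recurrence and verified in the tests against
a full enumeration oracle; no installed library exposes this primitive.
Imputed variants additionally require INFO > 0.1 and MAF > 0.005, and
individual calls with maximum genotype probability ≤ 0.80 are set to
missing (a per-variant aggregate alternative is available behind a flag,
since per-genotype vs per-variant semantics are a genuine ambiguity).
F_het is only meaningful on panels of thousands of variants; on a PRS-size
panel (~84 variants) the estimate is noise, and the analysis drivers skip
sample QC in that situation.

The PRS is the unstandardised weighted allele count
`score_i = Σ_v β_v · dosage_i(effect)`. Weights are matched to variants by
rsID and allele identity; when the effect allele is the reference allele
the dosage is flipped via `dosage(effect) = 2 − dosage(alt)`.
Strand-ambiguous A/T and C/G pairs are matched by identity with a warning
— no frequency-based strand inference is attempted, because curated PRS
panels are expected to be strand-aligned. Missing dosages are imputed as
2 × cohort effect-allele frequency, which keeps scores comparable across
samples; fewer than 50% matched weights is an error (it indicates a
genome-build or naming mismatch, and silently scoring half a panel is
worse than failing). Quartile cut points sit at the 25/50/75 percentiles
with ties assigned to the lower bin (deterministic, rank-convention);
constant scores degenerate to Q1 with a warning.

## Activity

Total METs = Σ intensity × sessions/week × minutes/session over reported
activities. Per-activity MET intensities are caller-supplied (the bundled
defaults cover common leisure activities in the spirit of the activity
compendium, since no canonical table is part of the analysis). The
active/less-active split is at 450 MET·min/wk, with the boundary counted
as active — matching the "METs ≥450" subgroup labelling.

## Subgroup statistics

Every subgroup yields a 2×2 table of cases/controls inside vs outside.

* **Odds ratio** (a/b)/(c/d) with the Woolf log-normal CI
  `exp(log OR ± z·√(1/a+1/b+1/c+1/d))` and the conventional two-sided
  Fisher exact p (sum of table probabilities at most that of the observed
  table, delegated to scipy). The Woolf CI was chosen because it
  reproduces the published intervals where exact conditional CIs do not;
  across the 54 published CI bounds, 53 agree to the printed rounding and
  one (the age ≥35 parent lower bound) lands one unit of the last digit
  away (2.045 vs a printed 2.1). A zero cell triggers the
  Haldane–Anscombe +0.5 correction for the OR/CI only, flagged in the
  result; a zero margin is an error.
* **Positive LR** = (cases_in/controls_in) / (reference cases/controls),
  the reference being the whole cohort or the subgroup's parent. It is the
  ratio of posterior to prior odds of diagnosis.
* **Bootstrap.** Participants are resampled with replacement; because all
  statistics depend on the data only through the joint counts of
  (outcome × child × parent membership), each replicate is drawn as a
  single multinomial over those ≤6 categories — exactly equivalent to row
  resampling, at O(n_boot) rather than O(n_boot·n). The CI is the
  2.5/97.5 percentile of the child-LR replicates. The p-value is the
  proportion of replicates in which the child LR falls on the null side
  of the parent LR (or of 1, for the whole-cohort comparison), with ties
  counting 0.5 (unbiased under exchangeability: a child identical to its
  parent gives p = 0.5 exactly). Replicates with an empty subgroup or
  undefined odds are dropped and counted, with a warning above 10%.

  The test direction is "auto" by default — chosen from the observed
  child-vs-parent comparison, which is how the published p-values read —
  but can be prespecified (`direction="greater"/"less"`). This matters
  for calibration: a post-hoc one-sided bootstrap p has a null
  distribution uniform on (0, 0.5), so it rejects at ≈2α; only the
  prespecified-direction p is uniform on (0, 1) and rejects at the
  nominal rate. `analysis/04_bootstrap_calibration.py` measures both
  (0.050 prespecified vs 0.102 auto at α = 0.05 over 500 null
  simulations). Consumers comparing a planned subgroup should prespecify;
  the auto mode exists to mirror the published usage and records the
  direction it chose.
* **Counts expansion.** `from_counts` rebuilds an individual-level cohort
  from one cross-classification at a time. The PRS-quartile × METs table
  determines all six joint design cells by subtraction, so that block
  expands to a fully consistent cohort. The clinical-covariate blocks
  (family history, age ≥35, BMI ≥25) publish only nested margins; sibling
  overlap inside a parent is unidentified and is assigned arbitrarily,
  which is immaterial because no computed statistic involves a sibling
  joint. Inconsistent inputs (child exceeding parent, partitions that do
  not sum) raise naming the violated pair, and re-deriving any table from
  the expansion returns the input counts exactly (tested as a round-trip
  property).

## Interaction model

`logit P(Y=1) = a + b·X1 + c·X2 + d·X3 + e·X4 + f·X3X4` with X1 = age,
X2 = BMI (optional confounders), X3 = top-PRS-quartile flag, X4 =
METs < 450 flag. The fit is plain maximum-likelihood logistic regression
(Newton, log-likelihood tolerance 1e-8, ≤100 iterations, via
statsmodels); a formulation that adds a Gaussian noise term inside the
logit is not estimable in this family and is deliberately not modelled —
the ordinary logit reproduces the published coefficients exactly, which
is the operational justification. The interaction p-value is the Wald
z-test on f (a coefficient-level test, matching how the result is
reported). Without confounders the two-binary-factor design is saturated:
coefficients equal the cell log-odds contrasts `a = logit(p00)`,
`d = logit(p10) − a`, `e = logit(p01) − a`,
`f = logit(p11) − a − d − e`, and fitted probabilities equal empirical
cell rates — both are asserted in the tests. Complete or quasi-complete
separation (a pure design cell) raises a diagnostic error rather than
returning diverged coefficients.

## Prediction harness

Stratified 10-fold cross-validation of an L2-regularised logistic
regression (C = 1.0 — an assumption of this harness, not a published
choice; any classifier with `predict_proba` can be passed in).
Out-of-fold probabilities are pooled; the AUC is the tie-corrected rank
statistic; the 95% CI is a 100-draw bootstrap over the pooled
(score, label) pairs (bootstrapping pooled pairs rather than CV folds is
a documented choice — the alternative resamples a quantity with only
n_folds atoms). Baseline features: age, BMI, race/ethnicity, family
history, PCOS, hypertension, waist (median-imputed with a missingness
indicator when absent); pregnancy-history features and HbA1c are
unavailable in a nulliparous first-visit setting and are omitted.
Published AUC levels require the original restricted cohort; the harness
is validated by properties (Mann–Whitney enumeration, monotone-transform
invariance, null AUC ≈ 0.5, and the ordering baseline+PRS ≥ baseline
whenever the generator gives the PRS a true effect).

## Synthetic cohorts

`simulate_cohort` draws: 84 independent biallelic variants with
frequencies U(0.1, 0.9) and positive weights scaled so the expected PRS
Σ 2fβ equals 8.3 on the raw scale (the realised SD lands near 0.55–0.65
without further adjustment); genotypes binomial(2, f); age N(28.6, 4.9²)
years; BMI N(26.5, 5.5²) kg/m² (a typical US nulliparous distribution —
the BMI marginal is not published); METs lognormal with (μ, σ) solved
from mean 900 / SD 950 MET·min/wk, giving the right-skew a mean≪SD
marginal implies; family history Bernoulli(0.18), the margin implied by
636/3533. The outcome is Bernoulli under the interaction logit with
default coefficients (b, c, d, e, f) = (0.10, 0.08, 0.41, 0.10, 0.78)
and the intercept solved numerically (Brent) so the expected prevalence
hits 3.7%; an unreachable target is an error. One global seed fans out to
fixed-offset child streams (via `SeedSequence(seed, spawn_key)`), so
adding a component never perturbs earlier draws and output is
byte-identical across runs.

What the generator does not emulate: linkage disequilibrium, ancestry
structure, genotyping batch effects, correlated covariates (age–BMI–METs
are drawn independently), reporting error in activity logs, and
longitudinal visits. Tests passing on synthetic data therefore
demonstrate correctness of the machinery and recoverability of effects
under the assumed model — not robustness to those real-data features.

`inject_missingness` masks entries completely at random and returns the
truth masks, so QC and eligibility filters can be checked against an
oracle that knows exactly what was removed.

## Problem sizes and numerics

The counts-expanded analyses run on the 3533-row cohort with 10,000
bootstrap replicates (sub-second per subgroup thanks to the multinomial
reformulation). The calibration experiment uses 500 null cohorts × 2,000
replicates; parameter recovery uses 100 synthetic cohorts of n = 50,000;
the CV-AUC demonstration uses n = 10,000. Floating-point comparisons in
the HWE and Fisher enumeration paths use a 1+1e-12 relative guard when
comparing probabilities for "at most as probable", avoiding
equal-probability tables being dropped by rounding.

## Known limitations

* The published bootstrap LR confidence intervals and p-values are
  reproduced only up to Monte-Carlo error and the original unknown RNG.
* The clinical-covariate count blocks cannot yield a single cohort
  carrying all three stratifications simultaneously (the three-way joints
  were never published); each block is expanded separately.
* The adjusted interaction model cannot be reproduced from printed counts
  (it needs individual-level age/BMI) and is validated by synthetic
  parameter recovery instead.
* Per-activity MET intensities are not standardised here; results depend
  on the caller's intensity table.
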