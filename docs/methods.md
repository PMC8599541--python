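# Methods

## Scientific setting

`swineclock` implements the analysis pipeline of a dual-species epigenetic
aging study: DNA-methylation age clocks for pigs (*Sus scrofa*) and for
pigs and humans jointly, epigenome-wide association studies (EWAS) of
chronological age across porcine tissues, a breed contrast between
domestic pigs and minipigs, and probe-set enrichment. The input is an
array-style beta-value matrix (per-CpG methylation fractions in [0, 1])
with a sample sheet (species, breed, tissue, sex, age) and a probe
annotation (position, nearest gene, TSS distance, CpG-island and
swine-mappability flags). Because the package is developed and tested
without access to array data, a synthetic-data module generates cohorts
with the statistical structure the analyses assume; its role and limits
are described below.

## Age transforms

Clocks regress a transformed age on methylation:

* **identity** — response is age in years (single-species pig clocks);
* **relative** — age divided by the species' maximum recorded lifespan
  (pig 23 y, human 122 y), aligning species of very different longevity on
  [0, 1];
* **log-linear** — for cross-species *chronological* clocks,
  `f(a) = log((a+k)/(m+k))` for `a <= m` and `f(a) = (a-m)/(m+k)` above,
  with maturity knot `m` and offset `k = 1`. The map is continuous with a
  continuous first derivative at the knot and has an exact inverse on both
  branches. Maturity defaults are pig 1 y and human 15 y — package
  defaults on the customary scale for each species, exposed in
  configuration (`AgeTransform.maturity_by_species`), not values taken
  from any particular cohort.

## Clock model and fitting

A clock is a sparse linear predictor over CpG beta values fitted by
elastic-net penalized least squares with the mixing parameter fixed at
alpha = 0.5 (midway between ridge and lasso). The penalty strength lambda
is chosen by internal ten-fold cross-validation over a descending grid of
100 log-spaced values from `lambda_max` (the smallest penalty giving the
all-zero model) down to `1e-3 * lambda_max`, minimizing mean CV squared
error; ties break toward the larger (sparser) lambda. The CV-minimum rule
rather than the one-standard-error rule is used because the study
procedure selects the penalty "automatically" by CV, and the minimum rule
is the plainer reading; the 1-SE alternative would give sparser clocks
with slightly worse CV error. Features are standardized internally (the
intercept is unpenalized via centering); reported coefficients are on the
original beta scale. Fold assignment is seeded, and stratified by species
for dual-species training so no internal fold is single-species.

The coordinate-descent solver is scikit-learn's `enet_path`, whose
objective `(1/2n)||y - Xb||^2 + lam*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2)`
matches the conventional glmnet parameterization on standardized features.

**Evaluation** is leave-one-sample-out cross-validation (LOOCV) with a
full refit — including the internal lambda search — for every held-out
sample, so the reported accuracy is not biased by penalty selection on the
full data. (The cheaper alternative, fixing one lambda for all folds, is
deliberately not used.) Accuracy is summarized by the Pearson correlation
R between held-out predictions and truth and the median absolute error
(mae), on the clock's natural scale: years for identity and log-linear
clocks, relative-age units for the relative clock. Per-tissue and
per-species breakdowns use the same held-out predictions.

**Dual-species clocks** concatenate the pig and human cohorts on their
shared probes and apply the species-aware transform per sample; a
relative-age clock therefore assigns a pig and a human with identical
shared-probe betas the same transformed prediction.

### Numerical choices

The solver runs in single precision at tolerance 1e-3 with at most 300
(acceptance runs) or 1000 (default) coordinate-descent sweeps per lambda.
This is ample for penalty selection and prediction on beta matrices, whose
meaningful signal is far above 1e-3; the small-instance equivalence checks
(closed-form ridge, generic-minimizer objective) run in float64 at 1e-12.
Zero-variance features keep scale 1 during standardization and can never
enter the model. A degenerate response (zero age variance) is an error.

## EWAS and meta-analysis

Within one tissue, each probe's betas are correlated with age (Pearson;
missing values dropped pairwise, per-probe n recorded). The statistic is
`t = r*sqrt(n-2)/sqrt(1-r^2)` with a two-sided Student p at n-2 df, and a
signed normal quantile `z = sign(r) * Phi^-1(1 - p/2)`, the form used for
meta-analysis. Zero-variance probes get r = 0, p = 1, z = 0; p-values are
floored at 1e-300 so z stays finite. Tissues are combined by Stouffer's
method, `z_meta = sum(w_i z_i)/sqrt(sum(w_i^2))`, with unit weights by
default; sqrt(n) weighting is available by flag since the original
weighting is unstated. Top-CpG selection keeps, among probes with
p < 1e-4, up to 500 per direction ranked by |z|, ties broken by probe id
for determinism. Genomic-context summaries report TSS-distance-bin and
CpG-island composition of a top set against a background, plus mean and
median association z inside and outside islands.

## Breed comparison

On the blood cohort (domestic 98, minipig 60; domestic is the reference
level), two OLS models are fitted per CpG: `beta ~ age + breed` (shared
aging and baseline breed effects) and `beta ~ age + breed + age x breed`
(rate differences). Coefficient Z statistics use the normal approximation
(the per-probe residual df is ~150; exact Student t is available by flag).
Calls: shared aging and breed baseline at p < 1e-8; interactions at 5% FDR
by Benjamini–Hochberg (the field-default step-up procedure, as the FDR
method is unstated). Each significant interaction CpG is categorized by
binning each breed's stratified aging Z at ±1.96 into hyper/hypo/ns; the
3x3 grid minus the doubly-ns cell yields eight categories (doubly-ns
probes are labeled `discordant-unclassified`). The ±1.96 bin edge is a
configurable package default; no particular value is prescribed by the
study.

Note an identifiability point surfaced by simulation: a CpG whose aging
*slopes* differ between breeds generally also differs in *mean* level at
the average age, so model 1's breed term fires on true interaction CpGs.
This is correct behavior, not a false positive; recovery tests therefore
judge the baseline call set on the non-interaction universe.

## Enrichment, GWAS overlap, classifiers

Probe-set enrichment per term (e.g. a transcription-factor motif) is the
upper hypergeometric tail P(X >= k) for k foreground hits out of n drawn
from a background of N containing K term probes. No CG-content correction
is applied, and the background is an explicit input (typically the
mappable or same-gene-mapped probe universe). GWAS overlap is a
case-insensitive gene-symbol set operation that reports, per overlapping
gene, which EWAS sets implicate it and its smallest-p SNP. The cohort
classifiers are random forests (500 trees, sqrt(p) features per split,
seeded) whose accuracy is the out-of-bag error computed from OOB votes.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study's sampling design: 82 domestic blood,
60 minipig blood, and 16 samples per tissue (blood, bladder, frontal
cortex, kidney, liver, lung) from a domestic x minipig cross — 238 pig
samples, ages 0.02–6.26 y with right-skewed per-cell age distributions
matched to the cohort means — plus an optional human companion cohort
(default ages 0–93 y across four tissues). The published table lists 15
samples for two of the cross tissues but 16 per tissue elsewhere and a
total of 238; the generator uses 16 per cross tissue, which reproduces
both the 238 total and the 98-vs-60 blood breed contrast.

Per-probe betas are `clip01(baseline + slope * g(age) + breed_offset +
interaction + signatures + N(0, noise_sd))`:

* baselines are bimodal (islands low, non-islands mostly high);
* a fraction `frac_age_cpgs` (default 0.10) of probes drift with age,
  hypermethylating with probability 0.8 when in a CpG island;
* a fraction `frac_shared_across_species` (default 0.5) of age CpGs track
  **relative age** in every species, which is what makes a joint
  relative-age clock learnable; non-shared age CpGs are
  species-restricted — pig-only CpGs are linear in chronological age,
  and human-only CpGs follow the human log-linear age curve, emulating
  the early-life methylation drift that saturates after maturity (the
  reason log-linear transforms exist);
* minipigs get a +0.02 island-baseline shift and `n_breed_baseline_cpgs`
  (default 20) constant offsets of ±0.08; `n_interaction_cpgs` (default
  10) have per-breed slopes with guaranteed rate differences, the first
  two forced to opposite signs (the divergent pattern);
* tissue- and sex-signature CpGs carry constant class offsets (0.2 and
  0.1), giving the near-perfect class separability real methylation
  cohorts show;
* `slope_scale` = 0.5 beta-units per unit scaled age and `noise_sd` = 0.02
  beta-units. These were fixed once at design time against the
  closed-form power of the correlation t-test: at the domestic-blood size
  (n = 98) the implied per-CpG |r| is >= 0.6, where the p < 1e-4 screen
  has essentially full power, which is the regime the study's screens
  operate in.

All randomness flows from one seeded generator; outputs are
bit-reproducible.

What the generator does **not** emulate: array chemistry and batch
effects, probe cross-reactivity, beta-value heteroscedasticity near the
boundaries (noise is homoscedastic Gaussian before clipping), nonlinear
per-CpG trajectories (a logistic option exists but is off by default),
sex chromosomes, and correlation between neighboring probes. Passing
accuracy regimes on this generator therefore shows that the *pipeline*
recovers structure it is designed for at realistic sizes and noise —
not that real porcine arrays would yield the same numbers.

## Problem sizes for tests and acceptance runs

The package's own study-scale runs use desk-scale probe counts chosen so a
full LOOCV (hundreds of complete elastic-net refits with internal CV)
stays cheap on one core: 800 probes for the pig clock run, 640 for the
dual-species runs (with a 200-sample human cohort standing in for the full
reference cohort), 600 for the classifiers, and 30,000 probes for the
null error-control screen (where only one correlation pass is needed).
Clock accuracy at these sizes is driven by the number of informative CpGs
relative to noise, not by the total probe count, so results are stable in
the probe count once a few dozen age CpGs are present.

## Known limitations

* LOOCV with a re-run lambda search is O(n^2 p L) and dominates runtime;
  the published-scale probe count (34,540 mappable probes) is out of desk
  range but changes nothing structurally.
* The breed models assume homoscedastic Gaussian residuals; beta values
  near 0/1 violate this, and a logit/M-value option is not provided.
* Published CpG counts that depend on the proprietary array data (e.g.
  clock CpG lists, or the 10,167 / 825 / 32 breed-model calls) are not
  reproducible from synthetic data and are not targeted; the package
  reproduces the procedures and the accuracy regime.
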