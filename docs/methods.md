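# Methods

`dnamet` implements a pipeline for building DNA-methylation (DNAm)
surrogates of blood ¹H-NMR metabolomics features across heterogeneous
cohorts, and for evaluating those surrogates as mortality predictors.
Because the cohort data such a study uses are access-restricted, the
package ships a first-class synthetic multi-cohort generator with known
ground truth; every downstream stage is developed and validated against
that ground truth.

## Synthetic multi-cohort generator

Each cohort has its own age, BMI and sex marginals. Log-metabolite
concentrations are linear in z-scored age, BMI and sex plus a shared
latent factor (inducing inter-metabolite correlation) and Gaussian
noise, then exponentiated — concentrations are therefore positive and
right-skewed, and the pipeline's log + z transform recovers Gaussian
structure. Methylation beta values arise as
`inverse-logit(b0_j + w_j · z_met + ε_j)` for each metabolite's causal
CpGs, with `b0_j ~ N(0,1)` and logit noise σ = 0.3 by default; a
disjoint 5% slice of the remaining CpGs carries age/sex signal and the
rest are pure noise. Keeping age/sex effects off the causal CpGs makes
the variance a metabolite's causal set can explain available in closed
form: the linearised best-linear-predictor R² is `S/(1+S)` with
`S = Σ_j w_j²/σ²` (the inverse-logit slope cancels from numerator and
denominator), and `effect_sd_for_r2` inverts this to pick the weight
scale for a target R². Defaults (16 metabolites, 20,000 CpGs, 200
causal CpGs per metabolite) preserve the structure of an array-scale
study at desk scale.

Batch effects are injected on the raw concentration scale — where the
calibration operates — as a per-cohort per-feature affine map
`x' = (x − m)·factor + m + delta` around the cohort-feature mean.
Survival times invert the Weibull-baseline proportional-hazards
survivor function `S(t|x) = exp(−(t/scale)^shape · e^{x'β})` at a
uniform quantile, with β applying to z-scored log-metabolites (defaults:
shape 1.5, scale 30 y, four true drivers with log-HRs 0.4/0.3/0.3/0.2).
Censoring is administrative-uniform on `[0, T_max]`, with `T_max`
solved by bisection to approximate the configured censored fraction —
approximate by design, documented rather than exact. All draws come
from one seeded generator, so equal configs give byte-identical data.

What the generator does *not* emulate: the Nightingale panel's real
feature-by-feature covariance, family/twin structure, cell-type
composition effects on methylation, and genuine non-linear
phenotype–metabolome relations. Tests passing on this generator
therefore certify the *mechanics* of the pipeline (no leakage, correct
estimators, exact algebra), not field performance on real cohorts.

## Metabolomics QC

Fixed order, tested for idempotence: (1) drop any feature whose missing
fraction exceeds 0.3 in *any* cohort (strict inequality; the threshold
generalises the precedent of removing a feature that was 80% missing in
one cohort); (2) flag cells with robust `|x − median|/(1.4826·MAD) > 5`
per feature, on the log scale by default (the robust-z form and
threshold are our choice; both scale and threshold are configurable);
(3) remove samples with more than one flagged feature; (4) impute
remaining missing cells with missing-aware NIPALS (5 components,
tolerance 1e-6), refined to self-consistency by alternating rank-k PCA
of the completed matrix with re-estimation of the missing cells — the
refinement removes the small bias a single pass inherits from
observed-only column means, driving exact-rank recovery to the
tolerance; (5) log-transform and z-score per feature across all pooled
samples. Values under the detection limit are kept by default
(`set_missing` offered). Because NIPALS is an unconstrained linear
model, imputed concentrations can dip below zero;
`impute_concentrations` floors imputed cells at half the smallest
observed value of their feature so the log transform stays defined.
Only imputed cells are ever altered.

## Cross-cohort calibration

Assumption: phenotypically similar individuals have similar
metabolomes. Each non-reference cohort is matched to the reference
sex-exactly and by greedy nearest neighbour without replacement on
(age, BMI) standardised by the reference SDs, accepting pairs in order
of increasing distance under a 0.5-SD caliper, then truncating to equal
male and female pair counts (worst pairs dropped). The greedy-global
order and id-based tie-breaks make matching deterministic. Per feature,
the calibration map stores matched-subset means and SDs of target and
reference; applying `x' = (x − μ_t)/σ_t · σ_r + μ_r` to *all* samples
of the cohort makes the matched-subset moments equal the reference's
exactly (an algebraic identity, tested at 1e-10) and is monotone.
As with imputation, the affine map can push an extreme low tail below
zero; `clip_floor="auto"` floors calibrated values at half the smallest
reference-cohort value per feature.

Residual batch structure is quantified two ways. A k-nearest-neighbour
mixing test (fixed k = 50, chi-square goodness of fit of each sampled
neighbourhood's cohort composition against global proportions, α =
0.05) reports the rejection rate; it is a simplified fixed-k
reimplementation of the kBET idea, used purely as a mixing diagnostic,
and is best read on the phenotype-matched subsets — on full cohorts
with genuinely different age structures, phenotype signal inflates the
rejection rate for reasons that are not batch. A principal
variance-component decomposition retains PCs to 90% variance,
attributes each PC to cohort/age/sex/BMI by single-factor R² (one-hot
for categoricals) with residual `1 − ΣR²` clipped at zero and
renormalised, and averages with eigenvalue weights — a fixed-effects
approximation of random-effects PVCA.

## Surrogate training

For one metabolic feature (log + z, calibrated): within each training
cohort an epigenome-wide scan regresses the feature on each CpG's beta
values separately (`feature ~ CpG`, no covariates), via the closed-form
correlation identities; zero-variance CpGs are omitted. Pre-selection
keeps CpGs whose slope has the same sign in every training cohort with
p < 0.05 in each — a deliberately permissive filter that enriches for
signal without a genome-wide threshold. The elastic net
(`(1/2n)‖y − b0 − Xb‖² + λ[α‖b‖₁ + (1−α)/2‖b‖₂²]`, α fixed at 0.5)
is solved by coordinate descent on internally z-standardised columns
(scikit-learn's solver; the objective matches exactly and KKT
stationarity is verified independently in tests to 1e-6), with a
100-point log-spaced λ grid from λ_max down to λ_max·1e-4.

Nesting: outer 5-fold CV stratified by cohort estimates generalisation;
within each outer-training set, pre-selection is computed once and an
inner 5-fold CV (also cohort-stratified) picks the λ minimising mean
validation MSE (no one-SE rule); the model refit at that λ predicts the
untouched outer fold. Pearson R and RMSE are reported per outer fold;
the final model recomputes pre-selection and λ on all training data.
Design points that were genuinely open and are settled here: running
pre-selection once per outer-training set rather than inside every
inner fold (the stricter variant is `preselect_in_inner=True`); cohort
stratification of folds; λ-selection by minimum mean MSE; variance
pre-filter off by default with a configurable SD floor. A per-fold
sample-id hash audit is stored in the performance report and asserted
in tests: no outer-test sample ever enters EWAS, pre-selection or λ
tuning for its fold. Accuracy tiers over mean test-set R: accurate
(R > 0.35), mildly accurate (0.2 < R ≤ 0.35), low (R ≤ 0.2); the middle
band's boundary inclusion is our resolution of an ambiguous printed
band, recorded here.

## Score projection

A `LinearScore` is an affine function of named features with a declared
preprocessing (optional log; z-scaling scoped `none`, `per_dataset`, or
`pooled` — the per-study mode mirrors applying a published score to
uncalibrated per-cohort data, the pooled mode fits calibrated data).
CpG-based models project as `intercept + Σ w_j β_j`, with CpGs absent
from the matrix imputed at reference mean betas (the count of imputed
CpGs is reported; a CpG absent from both matrix and reference is an
error). Published coefficient files are external inputs in the
documented JSON/TSV schema; the repository bundles only a synthetic
example (`examples/metabo_score.synthetic.json`). Projection is exactly
linear and serialisation round-trips bit-identically.

## Mortality models

The Cox partial likelihood with Efron tie correction is maximised by
Newton–Raphson with step halving to a gradient sup-norm of 1e-8;
standard errors come from the inverse observed information. The
implementation is pure numpy (sorted prefix sums; untied event groups
vectorised) and matches `lifelines` to ~1e-6 on the same data in tests;
monotone likelihood is detected both as coefficient divergence and as
the huge-coefficient/infinite-SE plateau, and raises with a suggestion
to penalise. Harrell's C counts pairs where the definite earlier
failure has the higher risk (score ties 0.5; equal-time pairs with two
events unusable; equal-time event/censored pairs count the event as
earlier) and equals an exhaustive enumeration oracle exactly in tests.

Univariate scans fit one age/sex-adjusted Cox model per z-scaled score
(HRs per SD), BH-adjust across scores, and report per-feature fit
failures (e.g., collinearity) without aborting. Stepwise composition
retains base covariates always, starts from the base model, and
alternates: add the candidate with the largest C gain if the gain
exceeds `tol_C = 0.001` and its Wald p < 0.05; otherwise remove the
least significant included variable (p > 0.05) whose removal costs at
most `tol_C`. The thresholds formalise a procedure described only
qualitatively in the literature this follows; every step is recorded in
a replayable trace, cycling stops with a warning, and re-entry after
removal is allowed. C-indices of two models on the same samples are
compared by a paired t-test on per-subject concordance contributions —
the spirit of the t-based comparison used with `survcomp`-style
estimators; the exact covariance estimator of that work is approximated
by the paired design, which the self-comparison and sign contracts pin
down. Time-dependent cumulative/dynamic AUC at a horizon uses IPCW
weights from the Kaplan–Meier censoring distribution
(scikit-survival); the proportional-hazards check is the
Grambsch–Therneau scaled-Schoenfeld score test with KM time transform
(lifelines, refit internally). Ties use Efron everywhere; no left
truncation (time since sampling).

## CpG characterisation

Positions are 1-based, region intervals half-open. CGI context:
island inside a (merged) island interval; shore within 2 kb of an
island edge; shelf within a further 2 kb; open sea otherwise — nearest
island governs, and every CpG gets exactly one label. Enrichment of a
CpG selection against annotation or trait sets uses the two-sided
Fisher exact test with odds ratio ad/bc (Haldane–Anscombe +0.5 when a
cell is zero) and BH across labels; trait catalogues are filtered at
load time to Bonferroni-significant associations (α / array size,
array size configurable, ≈480,000 by convention). Genes in cis link a
CpG to any gene interval within 100 kb inclusive. Cross-model overlap
is normalised by the smaller set (Jaccard also available); recurrent
CpGs are those selected in strictly more than `min_models` models,
reported with majority-sign agreement and the median rank of |weight|
within selecting models — |standardised coefficient| rank is our
importance definition, stated rather than inherited.

## Numerical and scale choices

- Elastic-net solves in the CV path use tolerance 1e-4 (warm-started);
  single fits checked against KKT conditions use 1e-7 or tighter.
- The k-NN mixing test includes the query point in its neighbourhood
  and fixes k; single-cohort input returns rate 0 with a warning.
- Analysis scripts and the acceptance script run three cohorts of
  500/500/900 samples, 8,000 CpGs and 8 metabolites (training), and
  criterion-style simulations at n = 1500–2000 with 30–200 replicates;
  these sizes are the package's desk-scale study conditions and are set
  in `analysis/config.py`.
- Matching ties are broken by sample-id order; all stochastic stages
  take explicit seeds; identical seeds give identical models, traces
  and scores.

## Known limitations

Real-cohort headline numbers (correlations, hazard ratios, C-indices of
published scores) require restricted data and are out of scope; the
generator's independence assumptions make the EWAS pre-selection easier
than on arrays with correlated probes; the PVCA and mixing diagnostics
are approximations of the cited random-effects and adaptive-k methods;
no competing risks, frailty, or left truncation in the survival layer;
DNAm array probe-level QC is assumed done upstream.
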