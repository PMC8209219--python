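# Methods

This note documents the statistical machinery of `phradiomics`, the
assumptions of the synthetic-data generator, the numerical choices, and
the limitations a user should understand before drawing conclusions
from passing tests.

## Synthetic cohort model

The generator (`phradiomics.cohort`) emulates a case-control imaging
study whose real data are not public.  Per mask (LV, RV) each subject
carries a latent feature vector

    x_latent = class_mean + subject_effect,   subject_effect ~ N(0, 1)

Informative features shift class means apart by `effect_size` (a
standardized mean difference; default 1.5).  An extraction replicate
observes

    x_obs = x_latent + e,   e ~ N(0, sd_f^2) independent per replicate,

plus a systematic `extraction_bias` (default 0.05) for replicates 2 and
3, emulating annotation drift.  `sd_f` is 0.15 for *stable* features and
1.5 for *unstable* ones, which puts their two-replicate ICCs near 0.98
and 0.31 — clearly on either side of the 0.75 "excellent" cut.  The
main study is a single extraction; side-study subjects' main values are
their first extraction, so replicate differences are purely a product of
the extraction process — the exact assumption DAFIT rests on.

Default conditions mirror the study design: 42 cases vs 40 controls,
348 features per mask laid out in the canonical texture-feature families
(9 histogram + 220 co-occurrence + 20 run-length + 5 gradient + 5
autoregressive + 73 geometrical + 16 wavelet), and a stratified side
study of 20 subjects per class (`frac_side_study = 0.4878`) with three
paired extractions.

The informative signal is deliberately concentrated in unstable
features: 1 stable + 19 unstable informative features per mask, and only
10% of noise features stable.  This embodies the scenario the framework
exists for — repeat-annotation studies typically find only a small
minority of radiomic features stable, and the predictive signal is not
confined to them.  With a majority-stable informative set every
approach saturates near AUC 1 and the approaches become
indistinguishable.  Noise features are generated in correlated blocks
(size 5, within-block r = 0.7) and include one exact duplicate column
and one exact two-column sum, so the correlation and linear-combination
filters have real work to do.

Confounders are drawn class-shifted: age +10 y, BMI +2.5, BSA +0.12 in
cases, hypertension prevalence 25% vs ~53%, all scaled linearly by
`confounder_strength` (0 ⇒ identical distributions).  LVEF is normal in
controls and a reduced/preserved mixture in cases, enabling the
preserved-EF (≥ 50%) subgroup path.

What the generator does **not** emulate: heavy-tailed or multiplicative
extraction noise, noise correlated across features or with disease
status, scanner/batch effects, and any real texture distribution.
Passing tests therefore demonstrate that the pipeline's logic and
bookkeeping are correct and that its statistical tests are calibrated —
not that DAFIT will outperform filtering on any particular real dataset.

### Image mode

`phradiomics.texture` provides a mechanistic alternative for small
studies: tiny 2-D images with binary masks, μ±3σ intensity
normalization, boundary-flip mask perturbation as a re-annotation
model, and a compact texture bank (9 histogram features; energy,
contrast, correlation, homogeneity, entropy per co-occurrence offset;
SRE/LRE/GLN/RLN/run-percentage from pooled run-length matrices).
Grey levels are quantized to 16 by default and co-occurrence offsets are
the four distance-1 directions; both are declared defaults, since the
original texture software's binning is not documented.  Features from
repeat perturbed annotations have ICC < 1 by construction, so the side
study's noise arises from the measurement process rather than from
simulated Gaussians.

## ICC

`compute_icc` implements the two-way mixed-effects single-rater
consistency ICC(3,1) from the ANOVA mean squares; re-annotation by the
same readers is a fixed-rater design, making consistency the natural
form.  The absolute-agreement form (which additionally charges the
rater variance component) is available via `form="agreement"`.  Notes:

* A constant offset between raters does not move the consistency ICC;
  only the agreement form can detect a systematic annotation shift.
* Zero-total-variance input returns 1.0 with a warning (trivially
  perfect agreement).
* Negative ICCs are retained as computed and always classify as poor.
* The printed agreement bands leave (0.74, 0.75] ambiguous; such values
  are classified `good` and flagged (`band_gap`) in the report.
* ICC2 uses a plain two-rater model on extractions 1–2 over the pooled
  (unstratified) side study; ICC3 requires excellence on all three
  pairwise two-rater models.

## DAFIT

Per feature, the three sets of ordered pairwise differences (1−2, 1−3,
2−3) over side-study subjects are concatenated (120 values for 40
subjects); μ is their sample mean and σ² the ddof-1 sample variance.  μ
is near zero but not forced to zero.  Augmentation adds independent
per-feature draws from N(μ, σ²) to each main-study row, twice, and the
modelling set is the 164 augmented rows only (a flag re-includes the
originals for sensitivity analysis).  Noise is marginal — no
cross-feature covariance, since the procedure defines only marginal
moments.  Noise streams are keyed by feature name, making augmentation
commute exactly with column permutation.  In the filtered variants
(Filt2/Filt3) the ICC filter is applied first and the noise profile
estimated on retained features only; this is configurable.

## Feature selection

All transforms are fit on the training fold only (train-statistics
standardization first; zero-variance columns map to 0) and applied
frozen to the held-out fold.  The high-correlation filter repeatedly
removes, from the worst-correlated remaining pair above the threshold,
the member with the larger mean absolute correlation (the classic
findCorrelation heuristic; strict ">" at the boundary).  The
linear-combinations filter is an incremental Gram–Schmidt sweep in
column order with tolerance 1e−8 relative to the largest column norm;
retained columns are full rank and removed ones exactly reconstructible.
PCA keeps the smallest component count whose cumulative explained
variance reaches the requested fraction.  Thresholds per approach and
mask scope follow the study's design table; the DAFIT-Filt approaches
exist only for the combined masks.

## Classifiers

Eleven models behind one fit/score contract (scikit-learn estimators):
"linear regression" fits least squares on 0/1 labels and scores by the
fitted value — legitimate because scores only feed the rank-based AUC.
nnet is a single-hidden-layer sigmoid network (lbfgs), mlp a ReLU
network; both are seeded.  Tuning grids are declared defaults (the
study publishes none): penalty strength on a log grid 1e−4…1e2 for
ridge/enet/lasso (elastic-net mixing 0.25/0.5/0.75), SVM cost
{0.1, 1, 10} with polynomial degree {2, 3}, hidden sizes {3, 5, 10}
with weight decay {1e−4, 1e−3, 1e−2}, random-forest mtry {√p, p/3},
GBRM depth {1, 2, 3} × {100, 300} trees.  Hyperparameters are chosen by
5-fold inner CV on AUC and refit on the full training fold; `tune=False`
fits the first grid point, which the screening harness uses.
Exclusions: linear/logistic/nnet never meet the rank-deficient full
set in the Original and DAFIT analyses, and linear/logistic skip the
corr-reduced DAFIT set for the same reason.

## Cross-validation and significance

Folds are assigned at the source-subject level, stratified by class
(round-robin within shuffled classes, so per-fold counts differ by at
most 1), five folds × five repeats = 25 estimates.  Augmented siblings
inherit their subject's fold, so augmentation cannot leak between train
and test.  AUC is the rank-based Mann–Whitney form with ties counted
1/2.  Splits with a single-class test set are recorded as missing and
excluded from summaries; a run fails if more than 20% of splits are
degenerate.  Model comparison uses the corrected resampled paired
t-test (variance inflated by 1/J + n_test/n_train with
n_test/n_train = 1/(k−1)); a paired sign-flip permutation test is
available behind a flag.  The permutation significance test permutes
subject labels, re-stratifies the fold plan per replicate, and reruns
the entire pipeline — selection inside splits included — B=100 times;
p = (#{null ≥ observed} + 1)/(B + 1), with floor 1/101 ≈ 0.0099.

## Confounder deviance partitioning

Within each CV test set, three logistic regressions of the observed
class are fit: confounder only, out-of-fold predictions only, both.
McFadden's pseudo-R² (1 − D_model/D_null) gives the deviance fraction
explained (Nagelkerke available behind a flag); LRT = D(confounder) −
D(both).  Fits use Newton/IRLS with a 1e−9 ridge, raised to 1e−4 under
(quasi-)separation so a finite deviance always exists.  Confounders are
assessed one at a time to avoid overfitting n≈16 test sets.  Because CV
test sets are dependent, significance is non-parametric: each of B=100
replicates permutes the outcome within every split, recomputes each
per-split LRT and takes the median; the observed median LRT is compared
against that null.  Components are summarized by their median over the
25 splits, with degenerate splits counted and excluded.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full-size cohort
(n=82, 348 features per mask, 696 combined) with the screening
configuration (`tune=False`, fixed default hyperparameters) for
permutation tests and multi-seed comparisons, and small purpose-built
cohorts for unit-level properties.  These sizes were chosen so the
complete analysis remains a minutes-scale desk computation while the
statistics of interest (permutation floors, calibration, approach
ordering) are unambiguous at them.

## Known limitations

* Under this generator the Original approach generally outperforms
  DAFIT: the main-study data are already correctly specified, so
  augmentation can only add noise to an otherwise clean problem, and
  DAFIT's 25 AUC estimates are computed on augmented (noisier) test
  rows.  DAFIT's advantage appears exactly where the framework predicts
  it: against the ICC-filtering approaches, which discard the unstable
  informative features outright.
* For the same reason, DAFIT_Filt2 and ICC2 are statistically
  indistinguishable here (their feature sets are identical and the
  augmentation noise on retained stable features is small); on real
  data the filtered-DAFIT advantage must come from noise structure this
  generator intentionally does not model.
* ICC confidence intervals, covariance-aware augmentation, supervised
  feature selection and external validation are out of scope.
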