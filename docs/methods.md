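# Methods notes

This note records the statistical model behind each stage of the
package, the defaults and why they were chosen, and the numerical
decisions that a maintainer would otherwise have to reverse-engineer.

## Data model

One row per trial: subject id, task (`implicit`/`explicit`), gaze
validity (`valid`/`invalid`, `not_applicable` on implicit object-absent
fillers), body-head congruency, object presence, binary correctness, and
confidence on the 11-point grid {0, 10, …, 100}. Factor levels are
stored as labels and converted to 0/1 codes only at model time
(0 = invalid, 0 = incongruent, 0 = low-AQ group), which prevents silent
coding flips between analyses. Object-absent fillers are kept at load
time and removed only by `filter_present_trials`, so overall-accuracy
summaries (including absent trials) remain computable.

AQ group is a median split on the sample median with ties assigned to
the **low** group. The tie rule is a package decision — with integer AQ
scores, ties at the median are common and some deterministic rule is
required for reproducibility.

## Synthetic generator

The generator emulates the study conditions the analyses assume:

* **Design**: 64 subjects; implicit task 12 object-present trials per
  validity × congruency cell plus 48 matched object-absent fillers;
  explicit task 48 trials per congruency level, all gaze-valid.
* **Accuracy**: Bernoulli draws under logistic models with per-subject
  random intercepts (SD 0.5 per task). Implicit fixed effects
  (intercept, validity, congruency, interaction) default to
  (1.01, 0.96, 0.99, −1.04) on the log-odds scale; explicit fixed
  effects (intercept, congruency, AQ slope per SD) to
  (1.72, 0.07, −0.20). These produce ~83% object-present implicit
  accuracy and ~84% explicit accuracy, with the validity benefit
  confined to body-head-incongruent cells
  (expit(1.01+0.96) ≈ 0.88 vs expit(1.01) ≈ 0.73 incongruent;
  0.87 vs 0.88 congruent). Object-absent fillers use a fixed 95%
  accuracy, giving ~89% overall implicit accuracy; they are
  generator-only and removed by the analysis filter.
* **Random slopes** default to SD 0 (intercept-only generation); the
  config exposes per-term slope SDs and an `explicit_trait_coupling`
  knob (adds a scaled copy of the subject's implicit interaction
  deviation to the explicit linear predictor) for the ordering- and
  transfer-recovery tests.
* **AQ**: rounded truncated-normal draws on [2, 27]. The target moments
  (mean 16.1, SD 6.08) describe the *observed bounded sample*, and with
  asymmetric bounds a naive `truncnorm(loc=16.1)` has truncated mean
  ≈ 15.76; the generator therefore solves for the pre-truncation
  location whose truncated mean equals the target. AQ z-scores are
  computed within sample, as the models z-score the covariate.
* **Confidence**: latent Gaussian
  `L = μ0 + (s0 + s_AQ·z(AQ))·correct + u_subject + ε`, discretized by
  equal-width cuts of `latent_range = (−2.5, 2.5)` onto the 11-point
  grid. Scaling is chosen so the *z-scored discrete* confidence behaves
  like a unit-variance response: with accuracy p̄ and slope s the
  marginal latent variance is s²p̄(1−p̄) + σ_u² + σ_ε², and setting it
  to 1 with σ_u = 0.3 gives σ_ε ≈ 0.73 (implicit, s = 1.66, p̄ ≈ 0.83)
  and σ_ε ≈ 0.86 (explicit, s = 1.17, p̄ ≈ 0.85). The intercepts
  μ0 = −s·p̄ (−1.38 / −1.00) center the latent scale, so the fitted
  standardized LMM recovers both the slopes and those intercepts.
  `s_AQ` defaults to −0.2 in the explicit task (type-2 coupling weakens
  with autistic traits; only the sign is dictated by the design, the
  magnitude is a package choice producing a clearly negative AUROC2–AQ
  rank correlation at n = 64) and 0 in the implicit task.
* **Reproducibility**: every random stream is keyed by
  (seed, subject index, purpose) through `numpy.random.SeedSequence`,
  so identical (config, seed) give byte-identical tables and enlarging
  the sample never perturbs earlier subjects' draws. The explicit task
  depends on the within-sample AQ z-score, so *explicit* trials
  legitimately change when the sample composition changes.

What the generator does **not** emulate: response times, sequential/
learning effects across blocks, stimulus-level variability (scene or
actor identity), miscalibration of confidence (over/under-confidence
biases beyond the latent shift), and any correlation between AQ and
implicit performance. Passing tests therefore demonstrate that the
*pipeline* recovers what it assumes, not that real data satisfy those
assumptions.

## Logistic mixed models

`fit_logistic_glmm` maximizes the Laplace-approximated marginal
likelihood over per-subject random effects with a **diagonal**
(uncorrelated) covariance: random intercept plus any fixed terms listed
as slopes. The maximal correlated structure is routinely singular at 12
trials per cell, so the diagonal parameterization is the default
contract; which slopes enter is controlled entirely by
`ModelSpec.random`.

Numerics: inner Newton with global step-halving solves all subjects'
conditional modes simultaneously on stacked arrays (grouped
`np.add.reduceat` reductions), warm-started across outer evaluations;
the outer L-BFGS-B optimizes (β, θ) with SD bounds [1e-6, 25] and
`ftol` 1e-13. The Laplace correction is computed as
−½ log|I + D·ZᵀWZ| per subject, which is stable as variance components
approach zero. Fixed-effect covariance is the inverse numerical Hessian
of the marginal NLL over β at the converged θ (the same convention as
standard mixed-model software), giving Wald z tests. Adaptive
Gauss-Hermite quadrature (default 7 nodes) is available for
intercept-only models and agrees with Laplace to ~1e-2 at this design
size. On ten frozen seeded datasets the fixed effects agree with an
independent reference mixed-model implementation to ≤ 1e-3.

Separation is detected by a coefficient-divergence guard
(|β| > 15 on the logit scale → diagnostic error). With
`pin_zero_variance=True` the model reduces exactly to pooled logistic
regression via Newton-Raphson IRLS — the degenerate-equivalence
contract (≤ 1e-6 relative against an independent GLM fit).

## Linear mixed model (confidence)

`fit_linear_lmm` estimates by REML, profiling β: per-subject Woodbury
identities on precomputed sufficient statistics (ZᵀZ, ZᵀX, Zᵀy, …)
make each evaluation O(m·q³). Confidence is z-scored within the
analysis sample before fitting (the model intercepts are then the mean
standardized confidence of incorrect trials). t tests use
**Satterthwaite** degrees of freedom: df = 2·var(β̂ⱼ)²/(gᵀAg) with g
the finite-difference gradient of var(β̂ⱼ) in the variance parameters
and A their asymptotic covariance from the numerical REML Hessian;
frozen reference values from an established Satterthwaite
implementation agree to ≤ 0.1 df. `pin_zero_variance=True` is exact
OLS with residual df.

The implicit-task confidence model is fit on object-present trials
only, mirroring the accuracy-analysis filter.

## Individual coefficients, transfer, comparison

A subject's coefficient for a term is the fixed estimate plus their
conditional mode (BLUP) for the matching random slope; modes average to
~0 across subjects, so the coefficient mean tracks the fixed estimate.
The two-stage transfer z-scores the per-subject implicit interaction
coefficients and enters them as a covariate (`implicit_accuracy`) in an
explicit accuracy GLMM with random intercept. The cross-task
coefficient comparison is a paired t test on (implicit interaction,
explicit congruency) per-subject coefficients with df = n − 1 (the
standard paired convention; with 64 subjects df = 63). When the
estimated slope variances are ~0 the per-subject vectors are nearly
constant and the paired t is numerically explosive while its sign and
the coefficient means remain meaningful — the acceptance script
therefore reports the two means rather than the degenerate t.

## Type-2 ROC / AUROC2

For each criterion c in {10, …, 100}, "high confidence" means rating
≥ c; the first criterion classes only 0 as low, the last only 100 as
high. The 10 (F, H) points are anchored at (0,0) and (1,1), sorted by
F (ties by H), and integrated trapezoidally. This construction is
algebraically identical to the pairwise statistic
P(conf_correct > conf_incorrect) + ½P(tie), which the package ships as
an independent brute-force oracle; the two agree to machine precision
(≤ 1e-12 enforced). Subjects with zero correct or zero incorrect
trials have undefined AUROC2, are flagged (not raised), and are dropped
from correlations with a logged count.

## Outliers, correlation, median split

Mahalanobis screening operates on the bivariate (AQ, AUROC2) plane:
squared distance from the sample mean under the sample covariance,
flagged above the chi-square(2) quantile at α = 0.025 (both the
variable set and cutoff are package choices exposed in config; the flag
rate calibrates to α on Gaussian clouds at n = 64 within sampling
error). Spearman correlation uses tie-averaged ranks with the
t-approximation p (t = ρ√((n−2)/(1−ρ²)), df = n − 2); the median-split
comparison is a pooled-variance two-sample t test reporting both the
two-sided p and the one-sided p for the directional hypothesis
(high-AQ < low-AQ), run on all subjects with defined AUROC2.

## Pipeline

Stages run in a fixed order (design validation → implicit accuracy
models and post hoc congruency split → explicit accuracy → transfer →
coefficient comparison → AQ models → confidence LMMs → metacognition),
all seeded from the single run seed; reports are written atomically and
identical seeds give identical reports (modulo wall-clock fields).
Significance thresholds default to two-sided 5%.

## Problem sizes

The test suite runs the full 64-subject design for single-fit checks,
100 seeded replicates for coefficient-recovery and AUROC2–AQ coupling
rates, 20 seeds for the dissociation pattern, 1,000 simulated subjects
for the oracle-equivalence and null-calibration checks, and 500
replicates for the Mahalanobis flag rate; larger-trial configurations
(100–500 trials per cell) are used where an ordering or closed-form
probability must be resolved deterministically. The acceptance script
averages five full-size replicate datasets per seed.

## Known limitations

* The GLMM covariance of fixed effects conditions on the estimated
  variance components (as is conventional); no Kenward-Roger-style
  small-sample correction is offered for the logistic models.
* Correlated random-effect covariance (the fully maximal structure) is
  out of scope; slopes are uncorrelated by construction.
* AUROC2 is criterion-sweep/nonparametric; no meta-d′ or hierarchical
  SDT metacognition models are provided.
* File-mode analysis expects the package's documented CSV schema;
  adapting external deposits requires mapping columns to it.
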