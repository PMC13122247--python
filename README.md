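# gazemeta

Behavioral-inference toolkit for **implicit vs. explicit gaze perception**:
hierarchical accuracy and confidence models, two-stage coefficient
transfer between tasks, and criterion-sweep Type-2 ROC metacognitive
sensitivity related to autistic traits.

## The problem

In a naturalistic gaze-cueing design, an actor in a photographed scene
looks at one of several objects while the actor's **body** is either
aligned with the turned head (*congruent*) or faces forward
(*incongruent*). Two tasks probe different routes of social attention:

* **implicit** — object detection under a task-irrelevant gaze cue; the
  cued object is present on half the trials and, when present, lies in
  the gaze direction (*valid*) or opposite (*invalid*);
* **explicit** — deliberate forced-choice judgment of where the actor is
  looking (all trials gaze-valid).

Each of 64 subjects completes 96 trials per task (implicit: 12
object-present trials per validity × congruency cell; explicit: 48 per
congruency level), rates confidence on an 11-point 0–100 scale, and
provides an Autism-Spectrum Quotient (AQ) score.

## The models

Accuracy is analyzed with logistic mixed models (Laplace-approximated
marginal likelihood; random intercept plus uncorrelated random slopes by
subject), e.g. for the implicit task

```
logit P(correct) = β0 + β1·validity + β2·congruency + β3·validity×congruency + b_subject
```

with factors coded 0/1 (0 = invalid / incongruent) and continuous
predictors z-scored. Confidence is analyzed with a REML linear mixed
model (`confidence_z ~ accuracy × AQ_z`, Satterthwaite df). Per-subject
coefficients (fixed effect + conditional mode) feed a two-stage transfer
analysis and a paired coefficient comparison across tasks.

Metacognitive sensitivity is **AUROC2**: sweep a confidence criterion
over the 11 levels, plot the hit rate P(high conf | correct) against the
false-alarm rate P(high conf | incorrect), and take the trapezoidal area
(0.5 = chance, 1 = perfect). AUROC2 is related to AQ by Spearman
correlation after bivariate Mahalanobis outlier screening
(chi-square(2) cutoff), plus an AQ median-split t test.

A seeded synthetic-data generator emulates the full design (trial
counts, logistic accuracy structure, AQ distribution, and a latent
confidence model whose accuracy coupling weakens with AQ in the explicit
task only), so every stage is testable without the original data.

## Worked example

```python
import gazemeta as gm
from gazemeta.pipeline import SPEC_IMPLICIT

cfg = gm.GeneratorConfig(seed=1)                 # 64 subjects, both tasks
subjects, trials = gm.generate_dataset(cfg)
implicit = gm.filter_present_trials(trials[trials["task"] == "implicit"])
fit = gm.fit_logistic_glmm(implicit, SPEC_IMPLICIT, subjects=subjects)
print(fit.summary_text(title="Implicit gaze perception accuracy"))
```

prints

```
Implicit gaze perception accuracy
Predictor                                      Estimate (SE)        z       df         p
Intercept                                       1.14 (0.12)     9.70             <0.001
gaze_validity                                   0.84 (0.14)     6.13             <0.001
body_head_congruency                            0.98 (0.14)     6.90             <0.001
gaze_validity:body_head_congruency             -1.03 (0.21)    -5.00             <0.001
```

The positive gaze-validity effect (β = 0.84) says subjects detect
gazed-at objects more often than opposite-side objects; the negative
validity × congruency interaction (β = −1.03) says that benefit is
confined to body-head *incongruent* scenes — the dissociation signature
the generator builds in (true values 0.96 and −1.04). Continuing,

```python
meta = gm.analyze_metacognition(trials, subjects, "explicit")
rho = meta["spearman_excluding_outliers"]
print(f"explicit AUROC2 vs AQ: rho={rho.rho:.3f}, t({rho.df})={rho.t:.2f}")
```

prints `explicit AUROC2 vs AQ: rho=-0.570, t(61)=-5.42`: subjects with
higher autistic traits show lower metacognitive sensitivity in the
explicit task (the implicit-task correlation is null by construction).

The same analyses are scriptable from the shell:

```sh
gazemeta simulate --seed 1 --out data/
gazemeta validate data/trials.csv
gazemeta run --seed 1 --out results/
```

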