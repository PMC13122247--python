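"""Mixed-model estimation: coding, degenerate equivalences, cross-checks,
individual coefficients and the two-stage transfer."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from gazemeta import (GeneratorConfig, extract_subject_effects,
                      fit_linear_lmm, fit_logistic_glmm, sample_subjects,
                      simulate_task, two_stage_transfer,
                      compare_coefficients_ttest, filter_present_trials,
                      generate_dataset)
from gazemeta.glmm import (FitError, ModelSpec, SeparationError,
                           _LaplaceObjective, build_design,
                           standardize_covariates)
from gazemeta.pipeline import (SPEC_CONFIDENCE, SPEC_EXPLICIT, SPEC_IMPLICIT)

FIXTURES = json.loads(
    (Path(__file__).parent / "data" / "lme4_fixtures.json").read_text())


# ---------------------------------------------------------------------------
# design construction

def test_factor_coding_enumerates_all_cells():
    data = pd.DataFrame({
        "subject_id": ["s"] * 4,
        "gaze_validity": ["valid", "valid", "invalid", "invalid"],
        "body_head_congruency": ["congruent", "incongruent"] * 2,
        "correct": [1, 0, 1, 0]})
    spec = ModelSpec(response="correct",
                     fixed=["gaze_validity", "body_head_congruency",
                            "gaze_validity:body_head_congruency"])
    _, X, _, _, _ = build_design(data, spec)
    assert list(X["gaze_validity"]) == [1, 1, 0, 0]
    assert list(X["body_head_congruency"]) == [1, 0, 1, 0]
    # interaction column is 1 exactly on the valid-congruent row
    assert list(X["gaze_validity:body_head_congruency"]) == [1, 0, 0, 0]


def test_standardize_and_zero_variance():
    z = standardize_covariates(np.arange(2, 28), "aq")
    assert z.mean() == pytest.approx(0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)
    with pytest.raises(FitError, match="aq"):
        standardize_covariates(np.full(10, 16.0), "aq")


# ---------------------------------------------------------------------------
# degenerate equivalences

def test_pinned_glmm_equals_pooled_logistic(implicit_present):
    fit = fit_logistic_glmm(implicit_present, SPEC_IMPLICIT,
                            pin_zero_variance=True)
    y, X, _, _, _ = build_design(implicit_present, SPEC_IMPLICIT)
    ref = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit()
    est = fit.params["estimate"].to_numpy()
    assert np.abs((est - ref.params) / ref.params).max() < 1e-6
    assert np.abs((fit.params["se"].to_numpy() - ref.bse) / ref.bse).max() < 1e-5


def test_pinned_lmm_equals_ols(implicit_present, dataset):
    subjects, _ = dataset
    fit = fit_linear_lmm(implicit_present, SPEC_CONFIDENCE,
                         subjects=subjects, pin_zero_variance=True)
    data = implicit_present.merge(subjects, on="subject_id")
    y, X, _, _, _ = build_design(data, SPEC_CONFIDENCE)
    ref = sm.OLS(y, X.to_numpy()).fit()
    est = fit.params["estimate"].to_numpy()
    assert np.abs((est - ref.params) / np.abs(ref.params)).max() < 1e-6
    assert np.abs((fit.params["se"].to_numpy() - ref.bse) / ref.bse).max() < 1e-6


# ---------------------------------------------------------------------------
# cross-implementation checks

@pytest.mark.parametrize("key", list(FIXTURES))
def test_estimates_match_reference_mixed_models(key):
    """Fixed effects agree with a reference mixed-model implementation
    (frozen lme4/lmerTest fits of the same seeded datasets) within 0.05."""
    fx = FIXTURES[key]
    cfg = GeneratorConfig(seed=fx["seed"])
    subjects, trials = generate_dataset(cfg)
    impl = filter_present_trials(trials[trials["task"] == "implicit"])
    expl = trials[trials["task"] == "explicit"]
    if fx["task"] == "implicit":
        fit = fit_logistic_glmm(impl, SPEC_IMPLICIT, subjects=subjects)
    elif fx["task"] == "explicit":
        fit = fit_logistic_glmm(expl, SPEC_EXPLICIT, subjects=subjects)
    else:
        fit = fit_linear_lmm(impl, SPEC_CONFIDENCE, subjects=subjects)
    est = fit.params["estimate"].to_numpy()
    assert np.abs(est - np.asarray(fx["estimate"])).max() < 0.05
    if "df" in fx:  # Satterthwaite df frozen from lmerTest
        assert np.abs(fit.params["df"].to_numpy()
                      - np.asarray(fx["df"])).max() < 1.0


def test_lmm_matches_statsmodels_mixedlm(implicit_present, dataset):
    subjects, _ = dataset
    fit = fit_linear_lmm(implicit_present, SPEC_CONFIDENCE,
                         subjects=subjects)
    data = implicit_present.merge(subjects, on="subject_id").copy()
    data["conf_z"] = standardize_covariates(data["confidence"])
    data["aq_zz"] = standardize_covariates(data["aq_score"])
    md = smf.mixedlm("conf_z ~ correct * aq_zz", data,
                     groups=data["subject_id"], re_formula="1",
                     vc_formula={"correct": "0 + correct"})
    ref = md.fit(reml=True)
    order = ["Intercept", "correct", "aq_zz", "correct:aq_zz"]
    assert np.abs(fit.params["estimate"].to_numpy()
                  - ref.fe_params[order].to_numpy()).max() < 0.05


def test_aghq_agrees_with_laplace(explicit_trials, dataset):
    subjects, _ = dataset
    spec = ModelSpec(response="correct", fixed=["body_head_congruency"],
                     random=["1"], family="binomial")
    lap = fit_logistic_glmm(explicit_trials, spec, subjects=subjects)
    agh = fit_logistic_glmm(explicit_trials, spec, subjects=subjects,
                            method="aghq", n_aghq=11)
    assert np.abs(lap.params["estimate"].to_numpy()
                  - agh.params["estimate"].to_numpy()).max() < 0.02


# ---------------------------------------------------------------------------
# estimation behaviour

def test_parameter_recovery_small(implicit_present, dataset, default_config):
    subjects, _ = dataset
    fit = fit_logistic_glmm(implicit_present, SPEC_IMPLICIT,
                            subjects=subjects)
    truth = dict(zip(
        ["Intercept", "gaze_validity", "body_head_congruency",
         "gaze_validity:body_head_congruency"],
        default_config.implicit_fixed))
    for term, true in truth.items():
        est = fit.params.loc[term, "estimate"]
        se = fit.params.loc[term, "se"]
        assert abs(est - true) < 3 * se, term


def test_separation_raises_diagnostic_error():
    data = pd.DataFrame({
        "subject_id": ["a", "a", "b", "b"] * 5,
        "gaze_validity": (["valid", "invalid"] * 10),
        "correct": ([1, 0] * 10)})
    spec = ModelSpec(response="correct", fixed=["gaze_validity"],
                     random=[], family="binomial")
    with pytest.raises(SeparationError):
        fit_logistic_glmm(data, spec, pin_zero_variance=True)


def test_inner_newton_increases_penalized_loglik(implicit_present):
    """The accepted inner steps never decrease the penalized likelihood."""
    y, X, Z, gidx, _ = build_design(implicit_present, SPEC_IMPLICIT)
    obj = _LaplaceObjective(y, X.to_numpy(), Z.to_numpy(), gidx)
    rng = np.random.default_rng(0)
    for _ in range(5):
        beta = rng.normal(0, 0.7, obj.p)
        dinv = 1.0 / rng.uniform(0.05, 1.0, obj.q) ** 2
        eta0 = obj.X @ beta
        pll0 = obj._pll(eta0, np.zeros((obj.m, obj.q)), dinv)
        obj._b[:] = 0.0
        b, _, pll, _ = obj.modes(beta, dinv)
        assert pll >= pll0 - 1e-9


def test_conditional_modes_center_and_shrink(implicit_present, dataset):
    subjects, _ = dataset
    fit = fit_logistic_glmm(implicit_present, SPEC_IMPLICIT,
                            subjects=subjects)
    modes = fit.conditional_modes
    assert np.abs(modes.mean(axis=0)).max() < 0.05
    coefs = extract_subject_effects(
        fit, "gaze_validity:body_head_congruency")
    fixed = fit.params.loc["gaze_validity:body_head_congruency", "estimate"]
    assert coefs.mean() == pytest.approx(fixed, abs=0.05)


def test_subject_effects_require_random_slope(explicit_trials, dataset):
    subjects, _ = dataset
    spec = ModelSpec(response="correct", fixed=["body_head_congruency"],
                     random=["1"], family="binomial")
    fit = fit_logistic_glmm(explicit_trials, spec, subjects=subjects)
    with pytest.raises(KeyError, match="random slope"):
        extract_subject_effects(fit, "body_head_congruency")


def test_subject_effect_ordering_recovers_truth():
    """Subjects simulated with stronger validity effects rank higher."""
    from gazemeta import spearman_with_t
    cfg = GeneratorConfig(
        n_subjects=40, trials_per_implicit_cell=150, seed=23,
        random_slope_sd={"implicit": {"gaze_validity": 0.8,
                                      "body_head_congruency": 0.0,
                                      "interaction": 0.0},
                         "explicit": {"body_head_congruency": 0.0}})
    subjects, effects = sample_subjects(cfg)
    trials = simulate_task(cfg, subjects, effects, "implicit")
    pres = filter_present_trials(trials)
    spec = ModelSpec(
        response="correct",
        fixed=["gaze_validity", "body_head_congruency",
               "gaze_validity:body_head_congruency"],
        random=["1", "gaze_validity"], family="binomial")
    fit = fit_logistic_glmm(pres, spec)
    est = extract_subject_effects(fit, "gaze_validity")
    truth = effects.set_index("subject_id")["b_implicit_gaze_validity"]
    rho = spearman_with_t(est[truth.index], truth).rho
    assert rho > 0.7


# ---------------------------------------------------------------------------
# two-stage transfer

def test_transfer_null_when_tasks_uncoupled(dataset):
    subjects, trials = dataset
    impl = filter_present_trials(trials[trials["task"] == "implicit"])
    expl = trials[trials["task"] == "explicit"]
    fit_impl = fit_logistic_glmm(impl, SPEC_IMPLICIT, subjects=subjects)
    res = two_stage_transfer(fit_impl, expl, subjects=subjects)
    beta = res.params.loc["implicit_accuracy", "estimate"]
    se = res.params.loc["implicit_accuracy", "se"]
    assert abs(beta) < 3 * se


def test_transfer_detects_induced_coupling():
    cfg = GeneratorConfig(
        n_subjects=48, seed=29,
        random_slope_sd={"implicit": {"gaze_validity": 0.0,
                                      "body_head_congruency": 0.0,
                                      "interaction": 0.8},
                         "explicit": {"body_head_congruency": 0.0}},
        explicit_trait_coupling=0.8)
    subjects, effects = sample_subjects(cfg)
    impl = filter_present_trials(
        simulate_task(cfg, subjects, effects, "implicit"))
    expl = simulate_task(cfg, subjects, effects, "explicit")
    fit_impl = fit_logistic_glmm(impl, SPEC_IMPLICIT, subjects=subjects)
    res = two_stage_transfer(fit_impl, expl, subjects=subjects)
    beta = res.params.loc["implicit_accuracy", "estimate"]
    assert beta > 0
    assert res.params.loc["implicit_accuracy", "p"] < 0.05


def test_transfer_rejects_misaligned_subjects(dataset):
    subjects, trials = dataset
    impl = filter_present_trials(trials[trials["task"] == "implicit"])
    expl = trials[trials["task"] == "explicit"].copy()
    fit_impl = fit_logistic_glmm(impl, SPEC_IMPLICIT, subjects=subjects)
    expl.loc[:, "subject_id"] = expl["subject_id"].str.replace("S0", "X0")
    with pytest.raises(FitError, match="X001"):
        two_stage_transfer(fit_impl, expl)


# ---------------------------------------------------------------------------
# paired coefficient comparison

def test_paired_ttest_identical_vectors_is_zero():
    a = pd.Series([0.1, -0.4, 0.3], index=list("abc"))
    res = compare_coefficients_ttest(a, a.copy())
    assert res.t == 0.0 and res.p == 1.0 and res.df == 2


def test_paired_ttest_constant_shift_guarded():
    a = pd.Series([0.1, -0.4, 0.3], index=list("abc"))
    with pytest.raises(ZeroDivisionError):
        compare_coefficients_ttest(a, a + 1.0)


def test_paired_ttest_matches_textbook_formula():
    a = np.array([0.5, 1.2, 0.8, 1.5, 1.0])
    b = np.array([0.2, 0.9, 0.9, 1.1, 0.6])
    d = a - b
    expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    res = compare_coefficients_ttest(a, b)
    assert res.t == pytest.approx(expected_t, rel=1e-12)
    assert res.df == 4
    assert res.mean_a == pytest.approx(a.mean())
    assert res.se_b == pytest.approx(b.std(ddof=1) / np.sqrt(5))


def test_paired_ttest_length_mismatch():
    with pytest.raises(ValueError, match="mismatch|align"):
        compare_coefficients_ttest(np.ones(4), np.ones(5) * 2)
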