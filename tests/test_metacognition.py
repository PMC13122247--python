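"""Type-2 ROC construction, AUROC2, outlier screening and correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazemeta.metacognition import (auroc2, auroc2_pairwise_oracle,
                                    mahalanobis_outliers,
                                    median_split_compare, spearman_with_t,
                                    subject_auroc2, type2_roc)

GRID = list(range(0, 101, 10))


def test_worked_example_auroc2_075():
    # correct {80,50,30} vs incorrect {50,20}: 4 wins + 1 tie over 6 pairs
    conf = [80, 50, 30, 50, 20]
    corr = [1, 1, 1, 0, 0]
    assert auroc2_pairwise_oracle(conf, corr) == pytest.approx(4.5 / 6)
    assert auroc2(type2_roc(conf, corr)) == pytest.approx(0.75, abs=1e-12)


def test_perfect_separation_hits_corner():
    conf = [100] * 4 + [0] * 3
    corr = [1] * 4 + [0] * 3
    roc = type2_roc(conf, corr)
    f, h = roc.points()
    assert any((fi == 0.0 and hi == 1.0) for fi, hi in zip(f, h))
    assert auroc2(roc) == 1.0
    assert auroc2_pairwise_oracle(conf, corr) == 1.0


def test_constant_confidence_is_diagonal():
    conf = [50] * 8
    corr = [1, 0] * 4
    assert auroc2(type2_roc(conf, corr)) == pytest.approx(0.5)
    assert auroc2_pairwise_oracle(conf, corr) == 0.5


def test_identical_distributions_are_chance():
    conf = [10, 40, 70, 100] * 2
    corr = [1] * 4 + [0] * 4
    assert auroc2_pairwise_oracle(conf, corr) == 0.5
    assert auroc2(type2_roc(conf, corr)) == pytest.approx(0.5, abs=1e-12)


def test_undefined_without_both_outcomes():
    roc = type2_roc([50, 60, 70], [1, 1, 1])
    assert not roc.defined
    assert np.isnan(auroc2(roc))
    assert np.isnan(auroc2_pairwise_oracle([50, 60], [1, 1]))


def test_curve_rates_monotone(dataset):
    _, trials = dataset
    one = trials[(trials["task"] == "explicit")
                 & (trials["subject_id"] == "S001")]
    roc = type2_roc(one["confidence"].to_numpy(), one["correct"].to_numpy())
    assert (np.diff(roc.hit) <= 1e-12).all()
    assert (np.diff(roc.fa) <= 1e-12).all()
    assert ((roc.hit >= 0) & (roc.hit <= 1)).all()


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.lists(st.tuples(st.sampled_from(GRID), st.integers(0, 1)),
                min_size=2, max_size=60))
def test_sweep_equals_pairwise_oracle(trials):
    conf = [c for c, _ in trials]
    corr = [y for _, y in trials]
    area = auroc2(type2_roc(conf, corr))
    oracle = auroc2_pairwise_oracle(conf, corr)
    if np.isnan(oracle):
        assert np.isnan(area)
    else:
        assert area == pytest.approx(oracle, abs=1e-12)


def test_confident_correct_trial_never_decreases_auroc2():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = rng.integers(6, 30)
        conf = rng.choice(GRID[:-1], n)  # leave headroom at 100
        corr = rng.integers(0, 2, n)
        if corr.min() == corr.max():
            continue
        before = auroc2(type2_roc(conf, corr))
        conf2 = np.r_[conf, 100]
        corr2 = np.r_[corr, 1]
        after = auroc2(type2_roc(conf2, corr2))
        assert after >= before - 1e-12


def test_off_grid_confidence_rejected():
    with pytest.raises(ValueError, match="grid"):
        type2_roc([55, 60], [1, 0])


def test_subject_auroc2_uses_present_trials_only(dataset):
    _, trials = dataset
    impl = trials[trials["task"] == "implicit"]
    per = subject_auroc2(impl)
    pres = impl[impl["object_present"]]
    counts = pres.groupby("subject_id")["correct"].agg(["sum", "size"])
    row = per.set_index("subject_id").loc["S001"]
    assert row["n_correct"] == counts.loc["S001", "sum"]
    assert row["n_correct"] + row["n_incorrect"] == counts.loc["S001", "size"]


# ---------------------------------------------------------------------------
# outlier screening

def test_far_point_flagged():
    pts = np.r_[np.random.default_rng(1).normal(0, 1, (40, 2)),
                [[25.0, 25.0]]]
    include, d2 = mahalanobis_outliers(pts, alpha=0.025)
    assert not include[-1]
    assert d2[-1] == d2.max()


def test_too_few_points_rejected():
    with pytest.raises(ValueError, match=">= 3"):
        mahalanobis_outliers(np.zeros((2, 2)))


def test_singular_covariance_rejected():
    pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
    with pytest.raises(ValueError, match="singular"):
        mahalanobis_outliers(pts)


def test_flag_rate_near_alpha():
    rng = np.random.default_rng(5)
    flagged = total = 0
    for _ in range(200):
        pts = rng.normal(0, 1, (64, 2))
        include, _ = mahalanobis_outliers(pts, alpha=0.025)
        flagged += (~include).sum()
        total += len(pts)
    assert 0.015 <= flagged / total <= 0.035


# ---------------------------------------------------------------------------
# correlations and group comparison

def test_spearman_perfect_and_reverse():
    x = np.arange(10.0)
    up = spearman_with_t(x, x ** 3)
    down = spearman_with_t(x, -x)
    assert up.rho == pytest.approx(1.0, abs=1e-12) and up.p < 1e-12
    assert down.rho == pytest.approx(-1.0, abs=1e-12)


def test_spearman_worked_example():
    # hand rank computation, no ties: d = (-1, 1, -1, 1, 0), sum d^2 = 4,
    # rho = 1 - 6*4 / (5*24) = 0.8
    res = spearman_with_t([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert res.rho == pytest.approx(0.8, abs=1e-12)
    assert res.t == pytest.approx(0.8 * np.sqrt(3 / (1 - 0.64)), rel=1e-9)
    assert res.df == 3


def test_spearman_constant_input_undefined():
    res = spearman_with_t([1.0, 1.0, 1.0], [1, 2, 3])
    assert np.isnan(res.rho) and np.isnan(res.p)


def test_median_split_null_is_small():
    rng = np.random.default_rng(8)
    vals = rng.normal(0.5, 0.1, 64)
    aq = rng.integers(2, 28, 64)
    res = median_split_compare(vals, aq)
    assert abs(res.t) < 3
    assert res.n_low + res.n_high == 64


def test_median_split_worked_example():
    aq = np.array([10, 12, 14, 20, 22, 24])
    vals = np.array([0.6, 0.55, 0.65, 0.4, 0.45, 0.35])
    res = median_split_compare(vals, aq)
    low, high = vals[:3], vals[3:]
    sp = np.sqrt(((low.var(ddof=1) + high.var(ddof=1)) / 2))
    expected_t = (high.mean() - low.mean()) / (sp * np.sqrt(2 / 3))
    assert res.t == pytest.approx(expected_t, rel=1e-9)
    assert res.median == 17.0
    assert res.p_one_sided == pytest.approx(res.p_two_sided / 2)


def test_median_split_degenerate_group_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        median_split_compare([1.0, 2.0, 3.0], [16, 16, 16])
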