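"""Ratio, IVW, MR-Egger, median and robust estimators."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit import (
    BootstrapConfig,
    InsufficientVariantsError,
    MRDataset,
    NonIdentifiableError,
    UndefinedRatioError,
    VariantAssociation,
    egger_estimate,
    ivw_estimate,
    median_estimate,
    ratio_estimate,
    robust_ivw,
    weighted_median,
)
from mrkit.estimators import VarianceModelConfig

from conftest import random_dataset

FIXED = VarianceModelConfig(model="fixed")
RANDOM = VarianceModelConfig(model="random_multiplicative")


def _wls_no_intercept(data):
    """Independent route: weighted no-intercept regression via lstsq."""
    sw = 1.0 / data.se_y
    X = (data.beta_x * sw)[:, None]
    y = data.beta_y * sw
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    se_fixed = float(np.sqrt(np.linalg.inv(X.T @ X)[0, 0]))
    return float(coef[0]), se_fixed


# ---------------------------------------------------------------------------
# Ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("by,bx,sey,expect_est,expect_se", [
    (0.5, 0.25, 0.1, 2.0, 0.4),
    (0.0, 0.3, 0.1, 0.0, 1.0 / 3.0),
    (0.243, -0.243, 0.05, -1.0, 0.05 / 0.243),
])
def test_ratio_examples(by, bx, sey, expect_est, expect_se):
    v = VariantAssociation("rs1", bx, 0.01, by, sey)
    est = ratio_estimate(v)
    assert est.estimate == pytest.approx(expect_est, abs=1e-12)
    assert est.se == pytest.approx(expect_se, abs=1e-12)


def test_ratio_undefined_for_zero_beta_x():
    v = VariantAssociation("rs9", 0.0, 0.01, 0.2, 0.05)
    with pytest.raises(UndefinedRatioError, match="rs9"):
        ratio_estimate(v)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

@settings(max_examples=120, deadline=None, derandomize=True)
@given(st.integers(0, 10_000_000))
def test_ivw_closed_form_equals_weighted_regression(seed):
    rng = np.random.default_rng(seed)
    data = random_dataset(rng, J=int(rng.integers(2, 20)))
    est = ivw_estimate(data, FIXED)
    reg_est, reg_se = _wls_no_intercept(data)
    assert abs(est.estimate - reg_est) < 1e-10
    assert abs(est.se - reg_se) < 1e-10


def test_ivw_single_variant_reduces_to_ratio():
    v = VariantAssociation("rs1", 0.25, 0.01, 0.5, 0.1)
    est = ivw_estimate(MRDataset([v]), FIXED)
    assert est.estimate == pytest.approx(2.0, abs=1e-14)
    assert est.se == pytest.approx(0.1 / 0.25, abs=1e-14)


def test_ivw_exact_fit_reports_underdispersion_and_truncates():
    theta = 0.7
    data = MRDataset.from_arrays([1.0, 2.0], [0.01] * 2,
                                 [theta, 2 * theta], [0.1] * 2)
    est = ivw_estimate(data, RANDOM)
    assert est.estimate == pytest.approx(theta, abs=1e-14)
    assert est.sigma_hat < 1  # untruncated residual scale reported (0 here)
    assert est.se == pytest.approx(ivw_estimate(data, FIXED).se, abs=1e-15)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000_000))
def test_random_effects_never_beat_fixed(seed):
    rng = np.random.default_rng(seed)
    data = random_dataset(rng, J=int(rng.integers(3, 15)), noise=1.0)
    assert ivw_estimate(data, RANDOM).se >= ivw_estimate(data, FIXED).se - 1e-15
    eg_r = egger_estimate(data, RANDOM).slope.se
    eg_f = egger_estimate(data, FIXED).slope.se
    assert eg_r >= eg_f - 1e-15


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000_000))
def test_egger_slope_se_at_least_ivw_se_fixed_model(seed):
    rng = np.random.default_rng(seed)
    data = random_dataset(rng, J=int(rng.integers(3, 15)))
    assert (egger_estimate(data, FIXED).slope.se
            >= ivw_estimate(data, FIXED).se - 1e-15)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def test_egger_collinear_through_origin_equals_ivw(toy_dataset):
    theta = 0.55
    bx = toy_dataset.beta_x
    data = MRDataset.from_arrays(bx, toy_dataset.se_x, theta * bx,
                                 toy_dataset.se_y)
    res = egger_estimate(data, FIXED)
    assert res.intercept.estimate == pytest.approx(0.0, abs=1e-12)
    assert res.slope.estimate == pytest.approx(
        ivw_estimate(data, FIXED).estimate, abs=1e-12)
    assert res.slope.estimate == pytest.approx(theta, abs=1e-12)


def test_egger_exact_affine_fit_recovered():
    a, b = 0.03, 0.8
    bx = np.array([0.05, 0.1, 0.2, 0.3])
    data = MRDataset.from_arrays(bx, [0.01] * 4, a + b * bx, [0.05] * 4)
    res = egger_estimate(data, RANDOM)
    assert res.intercept.estimate == pytest.approx(a, abs=1e-10)
    assert res.slope.estimate == pytest.approx(b, abs=1e-10)


def test_egger_requires_three_variants():
    data = MRDataset.from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
    with pytest.raises(InsufficientVariantsError):
        egger_estimate(data)


def test_egger_not_identified_with_equal_beta_x():
    data = MRDataset.from_arrays([0.2] * 4, [0.01] * 4,
                                 [0.1, 0.12, 0.09, 0.11], [0.02] * 4)
    with pytest.raises(NonIdentifiableError, match="identified"):
        egger_estimate(data)


def test_egger_matches_statsmodels_wls(toy_dataset):
    # independent oracle: statsmodels WLS with the same weights
    w = toy_dataset.se_y ** -2.0
    X = sm.add_constant(toy_dataset.beta_x)
    fit = sm.WLS(toy_dataset.beta_y, X, weights=w).fit()
    res = egger_estimate(toy_dataset, RANDOM)
    assert res.intercept.estimate == pytest.approx(fit.params[0], abs=1e-12)
    assert res.slope.estimate == pytest.approx(fit.params[1], abs=1e-12)
    # statsmodels reports the untruncated-sigma SEs; here sigma_hat < 1 so
    # the truncated SEs equal the fixed-model ones (sigma = 1)
    assert res.slope.sigma_hat == pytest.approx(
        np.sqrt(fit.scale), abs=1e-12)
    assert res.slope.se == pytest.approx(
        fit.bse[1] / min(np.sqrt(fit.scale), 1.0), abs=1e-12)


def test_egger_sensitive_to_single_flip_but_ivw_not(toy_dataset):
    flipped = list(toy_dataset.variants)
    v = flipped[2]
    flipped[2] = VariantAssociation(v.variant_id, -v.beta_x, v.se_x,
                                    -v.beta_y, v.se_y)
    data_f = MRDataset(flipped)
    assert abs(ivw_estimate(data_f, FIXED).estimate
               - ivw_estimate(toy_dataset, FIXED).estimate) < 1e-12
    with pytest.warns(UserWarning, match="orientation"):
        int_f = egger_estimate(data_f, FIXED).intercept.estimate
    int_0 = egger_estimate(toy_dataset, FIXED).intercept.estimate
    assert abs(int_f - int_0) > 1e-6


# ---------------------------------------------------------------------------
# Median methods
# ---------------------------------------------------------------------------

def test_weighted_median_interpolation_definition():
    # equal weights, odd count: the middle order statistic
    assert weighted_median(np.array([3.0, 1.0, 2.0]), np.ones(3)) == 2.0
    # equal weights, even count: mean of the central pair
    assert weighted_median(np.array([4.0, 1.0, 3.0, 2.0]), np.ones(4)) == 2.5
    # (essentially) all weight on one value
    assert weighted_median(np.array([1.0, 5.0, 9.0]),
                           np.array([1e-12, 1.0, 1e-12])
                           ) == pytest.approx(5.0, abs=1e-12)
    # hand-computed interpolation: values (1,2,3), weights (0.2,0.2,0.6);
    # s = (0.1, 0.3, 0.7); 0.5 sits between s_2 and s_3 -> 2 + 0.5
    assert weighted_median(np.array([1.0, 2.0, 3.0]),
                           np.array([0.2, 0.2, 0.6])) == pytest.approx(2.5)


def test_simple_median_of_ratios(toy_dataset):
    est = median_estimate(toy_dataset, "simple", BootstrapConfig(200, seed=1))
    ratios = toy_dataset.beta_y / toy_dataset.beta_x
    assert est.estimate == pytest.approx(np.median(ratios), abs=1e-14)


def test_simple_equals_weighted_when_variances_equal():
    # equal ratio-estimate variances: se_y proportional to |beta_x|
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    by = np.array([0.02, 0.09, 0.1, 0.22])
    data = MRDataset.from_arrays(bx, [0.01] * 4, by, 0.1 * bx)
    s = median_estimate(data, "simple", BootstrapConfig(200, seed=3))
    w = median_estimate(data, "weighted", BootstrapConfig(200, seed=3))
    assert s.estimate == pytest.approx(w.estimate, abs=1e-14)


def test_median_bootstrap_reproducible(toy_dataset):
    a = median_estimate(toy_dataset, "weighted", BootstrapConfig(500, seed=11))
    b = median_estimate(toy_dataset, "weighted", BootstrapConfig(500, seed=11))
    assert a.se == b.se and a.ci_lower == b.ci_lower


def test_median_rejects_zero_beta_x():
    data = MRDataset.from_arrays([0.1, 0.0, 0.3], [0.01] * 3,
                                 [0.05, 0.1, 0.15], [0.02] * 3,
                                 variant_ids=["a", "zero", "c"])
    with pytest.raises(UndefinedRatioError, match="zero"):
        median_estimate(data, "simple", BootstrapConfig(200, seed=1))


# ---------------------------------------------------------------------------
# Robust IVW
# ---------------------------------------------------------------------------

def test_robust_equals_ivw_on_exact_fit():
    theta = 0.6
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    data = MRDataset.from_arrays(bx, [0.01] * 4, theta * bx, [0.05] * 4)
    est = robust_ivw(data)
    assert est.estimate == pytest.approx(
        ivw_estimate(data, FIXED).estimate, abs=1e-8)


def test_robust_resists_gross_outlier():
    theta = 0.5
    rng = np.random.default_rng(4)
    bx = rng.uniform(0.1, 0.4, size=10)
    se_y = np.full(10, 0.02)
    by = theta * bx + 0.2 * se_y * rng.standard_normal(10)
    by[-1] += 0.3  # one gross pleiotropic outlier
    data = MRDataset.from_arrays(bx, [0.01] * 10, by, se_y)
    plain = ivw_estimate(data, FIXED).estimate
    robust = robust_ivw(data).estimate
    assert abs(plain - theta) / theta > 0.05
    assert abs(robust - theta) / theta < 0.05


def test_robust_large_tuning_limit_is_ivw(toy_dataset):
    est = robust_ivw(toy_dataset, tuning=1e8)
    assert est.estimate == pytest.approx(
        ivw_estimate(toy_dataset, FIXED).estimate, rel=1e-8)


def test_robust_point_estimate_close_to_statsmodels_rlm(toy_dataset):
    # independent cross-check on well-behaved data (initialization and
    # scale conventions differ, so agreement is approximate, not exact)
    sw = 1.0 / toy_dataset.se_y
    fit = sm.RLM((toy_dataset.beta_y * sw),
                 (toy_dataset.beta_x * sw)[:, None],
                 M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
    est = robust_ivw(toy_dataset)
    assert est.estimate == pytest.approx(float(fit.params[0]), rel=5e-2)


# ---------------------------------------------------------------------------
# Consistency under shrinking measurement error
# ---------------------------------------------------------------------------

def test_ivw_and_egger_consistent_as_noise_vanishes():
    from mrkit import ScenarioConfig, simulate_dataset
    theta = 0.3
    for se, tol in ((1e-3, 0.05), (1e-5, 5e-4)):
        cfg = ScenarioConfig(scenario="no_pleiotropy", J=40, theta=theta,
                             se_x_level=se, se_y_level=se, seed=5)
        data, _ = simulate_dataset(cfg)
        assert ivw_estimate(data, FIXED).estimate == pytest.approx(theta, abs=tol)
        assert egger_estimate(data, FIXED).slope.estimate == pytest.approx(
            theta, abs=10 * tol)
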