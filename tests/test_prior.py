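import numpy as np
import pytest
from scipy.stats import norm

from verticality.prior import (
    DEFAULT_HAPTIC_PRIOR_FIT,
    DEFAULT_VISUAL_PRIOR_FIT,
    FLAT_ALL,
    UPRIGHT_ALL,
    UPRIGHT_CHILDREN_FLAT_ADULTS,
    UPRIGHT_CHILDREN_UPSIDEDOWN_ADULTS,
    LikelihoodAgeParams,
    PriorConfig,
    PriorModelSearch,
    fit_prior_model,
    forward_predict,
    posterior_peak,
    predicted_bias,
    rectify_sigma,
    sigma_age,
)

AGES = np.array([6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 29.5])


def grid_peak(mu_p, sigma_p, mu_l, sigma_l, lo=-200.0, hi=20.0, step=0.01):
    """Independent oracle: argmax of the numerically evaluated prior x
    likelihood product on a fine linear grid."""
    theta = np.arange(lo, hi + step / 2, step)
    product = norm.pdf(theta, mu_p, sigma_p) * norm.pdf(theta, mu_l, sigma_l)
    return theta[int(np.argmax(product))]


@pytest.mark.parametrize(
    "age, a0, a1, expected",
    [
        (25.0, 5.3, 0.16, 9.3),
        (13.0, 7.0, 0.0, 7.0),
        (6.0, 0.3, -0.16, -0.66),
    ],
)
def test_sigma_age_linear_in_age(age, a0, a1, expected):
    assert sigma_age(age, LikelihoodAgeParams(a0, a1)) == pytest.approx(expected)


def test_rectify_all_positive_adds_epsilon_only():
    raw = np.array([5.0, 6.0, 9.0])
    np.testing.assert_allclose(rectify_sigma(raw, 0.1), raw + 0.1)


def test_rectify_negative_minimum_shifts_and_preserves_order():
    params = LikelihoodAgeParams(0.3, -0.16)
    raw = sigma_age(np.array([6.0, 10.0, 20.0, 37.0]), params)
    out = rectify_sigma(raw, 0.1)
    assert np.all(out > 0)
    assert out[-1] == pytest.approx(0.1)  # oldest age maps to epsilon
    assert np.all(np.diff(out) < 0)  # decreasing trend preserved


def test_rectify_constant_positive():
    np.testing.assert_allclose(rectify_sigma(np.array([2.0, 2.0]), 0.1), 2.1)


def test_posterior_peak_flat_prior_returns_likelihood_center():
    assert posterior_peak(None, 10.0, -90.0, 5.0) == -90.0


def test_posterior_peak_equal_widths_is_midpoint():
    assert posterior_peak(0.0, 7.0, -90.0, 7.0) == pytest.approx(-45.0)


def test_posterior_peak_matches_grid_oracle_visual_case():
    peak = posterior_peak(0.0, 24.7, -90.0, 9.4)
    assert peak == pytest.approx(grid_peak(0.0, 24.7, -90.0, 9.4), abs=0.02)
    assert predicted_bias(peak) == pytest.approx(-11.39, abs=0.05)


def test_posterior_peak_matches_grid_oracle_random_draws():
    rng = np.random.default_rng(31)
    for _ in range(100):
        mu_p = rng.choice([0.0, -180.0])
        sp = rng.uniform(1.0, 60.0)
        sb = rng.uniform(0.3, 40.0)
        peak = posterior_peak(mu_p, sp, -90.0, sb)
        assert peak == pytest.approx(grid_peak(mu_p, sp, -90.0, sb), abs=0.02)


@pytest.mark.parametrize(
    "peak, expected",
    [(-90.0, 0.0), (-78.7, -11.3), (-100.0, 10.0)],
)
def test_predicted_bias_sign_convention(peak, expected):
    assert predicted_bias(peak) == pytest.approx(expected)


def test_forward_flat_prior_predicts_no_bias():
    out = forward_predict(
        PriorConfig(FLAT_ALL, 1.0), LikelihoodAgeParams(5.0, 0.1), AGES
    )
    np.testing.assert_array_equal(out, 0.0)


def test_forward_tight_upright_prior_approaches_full_a_effect():
    out = forward_predict(
        PriorConfig(UPRIGHT_ALL, 1e-6), LikelihoodAgeParams(5.0, 0.1), AGES
    )
    np.testing.assert_allclose(out, -90.0, atol=1e-6)


def test_forward_wide_prior_washes_out():
    out = forward_predict(
        PriorConfig(UPRIGHT_ALL, 1e9), LikelihoodAgeParams(5.0, 0.1), AGES
    )
    assert np.max(np.abs(out)) < 1e-3


def test_reference_configs_reproduce_group_sign_pattern():
    """Visual: A-effects (negative) at every age.  Haptic: negative for
    children, positive for adults."""
    v = forward_predict(*DEFAULT_VISUAL_PRIOR_FIT, AGES)
    assert np.all(v < 0)
    h = forward_predict(*DEFAULT_HAPTIC_PRIOR_FIT, AGES)
    assert np.all(h[AGES < 18] < 0)
    assert np.all(h[AGES >= 18] > 0)


def test_bias_magnitude_monotone_in_prior_and_likelihood_width():
    """|bias| shrinks as the prior widens and grows as the senses noisen."""
    sb = 8.0
    biases = [
        predicted_bias(posterior_peak(0.0, sp, -90.0, sb)) for sp in (5, 10, 20, 40)
    ]
    assert np.all(np.diff(np.abs(biases)) < 0)
    sp = 20.0
    biases = [
        predicted_bias(posterior_peak(0.0, sp, -90.0, s)) for s in (2, 4, 8, 16)
    ]
    assert np.all(np.diff(np.abs(biases)) > 0)


SMALL_GRIDS = dict(
    sigma_p_grid=np.array([10.0, 20.0, 30.0]),
    a0_grid=np.array([2.0, 5.0, 8.0, 11.0]),
    a1_grid=np.array([-0.2, 0.0, 0.2]),
)


def test_fit_recovers_generating_grid_point_exactly():
    cfg = PriorConfig(UPRIGHT_ALL, 20.0)
    par = LikelihoodAgeParams(8.0, 0.2)
    obs = forward_predict(cfg, par, AGES)
    fit = fit_prior_model(AGES, obs, **SMALL_GRIDS)
    assert fit.config == cfg
    assert fit.params == par
    assert fit.sse == pytest.approx(0.0, abs=1e-18)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_prefers_flat_prior_for_zero_biases():
    fit = fit_prior_model(AGES, np.zeros_like(AGES), **SMALL_GRIDS)
    assert fit.config.policy == FLAT_ALL
    assert fit.sse == 0.0
    np.testing.assert_array_equal(list(fit.predicted_bias_by_age.values()), 0.0)


def test_fit_reports_r_squared_consistent_with_sse():
    cfg = PriorConfig(UPRIGHT_CHILDREN_FLAT_ADULTS, 20.0)
    par = LikelihoodAgeParams(8.0, -0.2)
    obs = forward_predict(cfg, par, AGES) + np.array([1, -1, 1, -1, 1, -1, 1.0])
    fit = fit_prior_model(AGES, obs, **SMALL_GRIDS)
    sst = float(((obs - obs.mean()) ** 2).sum())
    assert fit.r_squared == pytest.approx(1.0 - fit.sse / sst, abs=1e-12)
    assert fit.r_squared <= 1.0


def test_search_validates_inputs():
    with pytest.raises(ValueError, match="age groups"):
        PriorModelSearch([6.0, 8.0])
    with pytest.raises(ValueError, match="nonempty"):
        PriorModelSearch(AGES, sigma_p_grid=np.array([]))
    with pytest.raises(ValueError, match="policy"):
        PriorModelSearch(AGES, policies=["diagonal"])


def test_policy_split_applies_at_adult_age():
    cfg = PriorConfig(UPRIGHT_CHILDREN_UPSIDEDOWN_ADULTS, 20.0)
    par = LikelihoodAgeParams(8.0, 0.0)
    out = forward_predict(cfg, par, np.array([10.0, 17.9, 18.0, 30.0]))
    assert out[0] < 0 and out[1] < 0
    assert out[2] > 0 and out[3] > 0
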