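"""Profiles, confidence intervals, identifiability and validation profiles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chi2, norm

from conftest import make_flat_profile, make_quadratic_profile
from pl2design import fixtures
from pl2design.estimation import local_fit, neg2_log_likelihood
from pl2design.model import DataPoint, ExperimentalCondition, ValidationError
from pl2design.profiles import (
    IDENTIFIABLE,
    PRACTICALLY_NON_IDENTIFIABLE,
    STRUCTURALLY_NON_IDENTIFIABLE,
    average_ci_width,
    classify_identifiability,
    confidence_interval,
    profile_parameter,
    validation_profile,
)

THR95 = chi2.ppf(0.95, 1)  # 3.841459


# --- parameter profiles --------------------------------------------------------


def test_profile_minimum_is_zero_at_mle(line_setup):
    prof = profile_parameter(
        line_setup["model"], line_setup["data"], "a", fit=line_setup["fit"]
    )
    assert prof.pl_values.min() == pytest.approx(0.0, abs=1e-6)
    assert prof.beta_hat == pytest.approx(line_setup["fit"].theta_hat[0], abs=1e-9)


def test_linear_gaussian_profile_is_quadratic(line_setup):
    prof = profile_parameter(
        line_setup["model"], line_setup["data"], "a", fit=line_setup["fit"]
    )
    s = line_setup["s_a"]
    beta_hat = line_setup["fit"].theta_hat[0]
    expected = ((prof.beta_grid - beta_hat) / s) ** 2
    np.testing.assert_allclose(prof.pl_values, expected, atol=1e-3)


def test_profile_is_lower_envelope(line_setup):
    """PL(beta) <= -2 log LR at any fixed nuisance value."""
    model, data, fit = line_setup["model"], line_setup["data"], line_setup["fit"]
    prof = profile_parameter(model, data, "a", fit=fit)
    rng = np.random.default_rng(4)
    for beta, pl in zip(prof.beta_grid[::3], prof.pl_values[::3]):
        for b in rng.uniform(-2.0, 2.0, size=3):
            fixed = neg2_log_likelihood(model, [beta, b], data) - fit.objective
            assert pl <= fixed + 1e-9


# --- confidence intervals ------------------------------------------------------


def test_quadratic_profile_95_halfwidth():
    prof = make_quadratic_profile(s=1.0)
    ci = confidence_interval(prof, 0.95)
    assert ci.width / 2 == pytest.approx(1.959964, abs=1e-5)
    assert not ci.lower_open and not ci.upper_open


def test_zero_level_interval_degenerates():
    prof = make_quadratic_profile(s=0.7, beta_hat=1.2)
    ci = confidence_interval(prof, 0.0)
    assert ci.lower == ci.upper == pytest.approx(1.2, abs=1e-9)
    assert ci.width == 0.0


def test_flat_profile_clips_to_bounds_and_flags_open():
    prof = make_flat_profile(lo=-5.0, hi=3.0)
    ci = confidence_interval(prof, 0.9)
    assert (ci.lower, ci.upper) == (-5.0, 3.0)
    assert ci.lower_open and ci.upper_open


def test_too_short_profile_rejected():
    prof = make_flat_profile(n=2)
    with pytest.raises(ValidationError):
        confidence_interval(prof, 0.95)


def test_classification_three_regimes():
    assert classify_identifiability(make_quadratic_profile()) == IDENTIFIABLE
    assert (
        classify_identifiability(make_flat_profile())
        == STRUCTURALLY_NON_IDENTIFIABLE
    )
    # rises on the right only: no crossing on the left within bounds
    grid = np.linspace(-5.0, 3.0, 200)
    pls = np.where(grid > 0, (grid / 0.5) ** 2, 0.0)
    one_sided = make_flat_profile()
    one_sided.beta_grid, one_sided.pl_values = grid, pls
    one_sided.nuisance_at_beta = [None] * grid.size
    assert classify_identifiability(one_sided) == PRACTICALLY_NON_IDENTIFIABLE


# --- average confidence-interval width -----------------------------------------


def test_average_width_matches_numeric_integral():
    s = 0.8
    prof = make_quadratic_profile(s=s)
    oracle = quad(lambda a: 2 * s * norm.ppf((1 + a) / 2), 0, 0.95)[0]
    assert average_ci_width(prof, 0.95, 50) == pytest.approx(oracle, rel=1e-3)
    assert oracle == pytest.approx(1.36198 * s, rel=1e-4)


def test_average_width_uncapped_closed_form():
    s = 1.3
    prof = make_quadratic_profile(s=s, span=6.5, n=3201)
    w = average_ci_width(prof, alpha_max=1.0, n_alpha=4001)
    assert w == pytest.approx(s * np.sqrt(8 / np.pi), rel=2e-3)


def test_average_width_affine_equivariance():
    base = make_quadratic_profile(s=1.0)
    stretched = make_quadratic_profile(s=3.0, lo=-30, hi=30)
    w1 = average_ci_width(base, 0.95, 80)
    w3 = average_ci_width(stretched, 0.95, 80)
    assert w3 == pytest.approx(3.0 * w1, rel=1e-9)


def test_average_width_monotone_in_profile():
    lower = make_quadratic_profile(s=1.0)
    higher = make_quadratic_profile(s=1.0)
    higher.pl_values = 2.0 * higher.pl_values  # pointwise larger -2 log LR
    assert average_ci_width(higher, 0.95, 50) <= average_ci_width(lower, 0.95, 50)


# --- validation profiles -------------------------------------------------------


def test_vpl_linear_gaussian_closed_form(line_setup):
    model, data, fit = line_setup["model"], line_setup["data"], line_setup["fit"]
    cond = ExperimentalCondition("y", 5.0)
    vp = validation_profile(model, data, cond, fit=fit)
    xstar = np.array([5.0, 1.0])
    s_pred2 = line_setup["sigma"] ** 2 * xstar @ np.linalg.inv(
        line_setup["X"].T @ line_setup["X"]
    ) @ xstar
    expected = (vp.z_grid - vp.z_hat) ** 2 / (line_setup["sigma"] ** 2 + s_pred2)
    np.testing.assert_allclose(vp.vpl_values, expected, atol=1e-3)
    assert vp.z_hat == pytest.approx(fit.theta_hat @ xstar, abs=1e-8)
    # anchored at the current prediction
    i_hat = int(np.argmin(np.abs(vp.z_grid - vp.z_hat)))
    assert vp.vpl_values[i_hat] <= 1e-6
    assert np.all(vp.vpl_values >= -1e-6)


def test_vpl_vanishes_for_uninformative_sigma(line_setup):
    """A future point with huge sigma cannot degrade the fit: VPL -> 0."""
    model, data, fit = line_setup["model"], line_setup["data"], line_setup["fit"]
    cond = ExperimentalCondition("y", 5.0)
    z = fit.theta_hat @ np.array([5.0, 1.0]) + 1.0
    for sigma_z, bound in [(1.0, 1.1), (10.0, 0.02), (100.0, 2e-4)]:
        aug = data.append(DataPoint(cond, float(z), sigma_z))
        _, obj = local_fit(model, aug, fit.theta_hat)
        assert 0.0 <= obj - fit.objective < bound


def test_vpl_regularization_path():
    """A structurally unconstrained prediction gets the weak quadratic prior."""
    # one observation at t = 0 pins the intercept but leaves the slope free:
    # outcomes at t = 5 spanning b +- 50 all fit perfectly, so the raw VPL
    # stays flat far beyond the walker's reach
    spec = fixtures.line_reference_spec(xs=(0.0,), seed=5)
    data = fixtures.simulate_dataset(spec, seed=5)
    from pl2design.estimation import fit_mle

    fit = fit_mle(spec.model, data, n_starts=3, seed=0)
    vp = validation_profile(spec.model, data, ExperimentalCondition("y", 5.0), fit=fit)
    assert vp.regularized
    assert vp.reg_lambda > 0 and vp.reg_scale > 0
    assert vp.crossed == (True, True)  # the prior guarantees a finite sample space


def test_vpl_nonnegative_on_abc(abc_spec, abc_data, abc_fit):
    vp = validation_profile(
        abc_spec.model, abc_data, ExperimentalCondition("B", 40.0), fit=abc_fit
    )
    assert np.all(vp.vpl_values >= -1e-6)
    assert vp.crossed == (True, True)
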