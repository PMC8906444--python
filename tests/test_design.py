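"""Two-dimensional profiles, the design criterion, ranking and the sequential loop."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chi2, norm

from conftest import make_quadratic_profile
from pl2design import fixtures
from pl2design.design import (
    TwoDProfile,
    confidence_scale_export,
    expected_average_width,
    profile_2d,
    select_design,
    sequential_design,
)
from pl2design.estimation import fit_mle, local_fit
from pl2design.model import (
    DataPoint,
    Dataset,
    ExperimentalCondition,
    ValidationError,
)
from pl2design.profiles import average_ci_width, profile_parameter, validation_profile


@pytest.fixture(scope="module")
def line_twod(line_setup):
    cond = ExperimentalCondition("y", 5.0)
    return profile_2d(
        line_setup["model"], line_setup["data"], cond, "a", fit=line_setup["fit"]
    )


def _posterior_sd_a(line_setup, t_new=5.0):
    X = np.vstack([line_setup["X"], [t_new, 1.0]])
    cov = line_setup["sigma"] ** 2 * np.linalg.inv(X.T @ X)
    return float(np.sqrt(cov[0, 0])), X


def test_linear_rows_have_outcome_independent_width(line_twod, line_setup):
    """In a linear model the information of a point does not depend on its value."""
    assert np.ptp(line_twod.row_widths) < 1e-8
    s_post, _ = _posterior_sd_a(line_setup)
    analytic = quad(lambda a: 2 * s_post * norm.ppf((1 + a) / 2), 0, 0.95)[0]
    assert expected_average_width(line_twod) == pytest.approx(analytic, rel=0.02)


def test_linear_rows_match_conjugate_closed_form(line_twod, line_setup):
    """Each row is the quadratic profile around the refit slope, lifted by VPL(z)."""
    s_post, _ = _posterior_sd_a(line_setup)
    sigma = line_setup["sigma"]
    xstar = np.array([5.0, 1.0])
    s_pred2 = sigma**2 * xstar @ np.linalg.inv(
        line_setup["X"].T @ line_setup["X"]
    ) @ xstar
    for i in range(len(line_twod.z_rows)):
        z = line_twod.z_rows[i]
        Xa = np.vstack([line_setup["X"], xstar])
        ya = np.append(line_setup["data"].values(), z)
        beta_z = np.linalg.lstsq(Xa, ya, rcond=None)[0]
        prof = line_twod.row_profiles[i]
        expected = ((prof.beta_grid - beta_z[0]) / s_post) ** 2 + (
            z - line_twod.validation.z_hat
        ) ** 2 / (sigma**2 + s_pred2)
        np.testing.assert_allclose(line_twod.pl2d_row(i), expected, atol=1e-3)


def test_row_minimum_equals_vpl(line_twod):
    for i in range(len(line_twod.z_rows)):
        assert line_twod.pl2d_row(i).min() == pytest.approx(
            line_twod.row_vpl[i], abs=1e-3
        )


def test_decomposition_identity_linear(line_twod, line_setup):
    """PL2D(z, beta) = PL(beta | Y u z) + VPL(z), recomputed from scratch per cell."""
    model, data, fit = line_setup["model"], line_setup["data"], line_setup["fit"]
    cond = line_twod.condition
    for i in range(0, len(line_twod.z_rows), 4):
        z = line_twod.z_rows[i]
        aug = data.append(DataPoint(cond, float(z), line_twod.validation.sigma_z))
        theta_z, obj_z = local_fit(model, aug, fit.theta_hat)
        vpl_fresh = obj_z - fit.objective
        prof = line_twod.row_profiles[i]
        for j in range(0, len(prof), 5):
            beta = float(prof.beta_grid[j])
            _, obj_b = local_fit(model, aug, theta_z, fixed=(0, beta))
            pl_fresh = obj_b - obj_z
            assert line_twod.pl2d_row(i)[j] == pytest.approx(
                pl_fresh + vpl_fresh, abs=1e-3
            )


def test_expected_width_is_row_mean():
    rows = np.array([0.4, 0.4, 0.4, 0.4])
    twod = TwoDProfile(
        condition=ExperimentalCondition("y", 1.0),
        target_parameter="a",
        z_rows=np.arange(4.0),
        pred_levels=np.linspace(-0.9, 0.9, 4),
        row_profiles=[None] * 4,
        row_vpl=np.zeros(4),
        row_widths=rows.copy(),
        criterion_W=0.4,
        validation=None,
        budget=0,
    )
    assert expected_average_width(twod) == pytest.approx(0.4)
    twod.row_widths[2] += 0.2
    assert expected_average_width(twod) == pytest.approx(0.4 + 0.2 / 4)
    twod.row_widths = rows[:2]
    with pytest.raises(ValidationError):
        expected_average_width(twod)


def test_select_design_single_and_duplicate_candidates(line_setup):
    model, data, fit = line_setup["model"], line_setup["data"], line_setup["fit"]
    cond = ExperimentalCondition("y", 5.0)
    single = select_design(model, data, [cond], "a", fit=fit)
    assert single.selected == cond
    dup = select_design(model, data, [cond, ExperimentalCondition("y", 5.0)], "a", fit=fit)
    ws = [w for _, w in dup.entries]
    assert ws[0] == pytest.approx(ws[1], abs=1e-9)
    assert "tie" in dup.tie_note
    assert dup.selected == cond


def test_confidence_scale_export_levels(line_twod):
    df = confidence_scale_export(line_twod)
    assert set(df.columns) >= {"pred_level", "z", "beta", "param_conf"}
    for _, group in df.groupby("pred_level"):
        assert group["param_conf"].min() == pytest.approx(0.0, abs=1e-12)
    # a synthetic symmetric row maps the chi-square threshold to its level
    prof = make_quadratic_profile(s=1.0, n=201)
    twod = TwoDProfile(
        condition=line_twod.condition,
        target_parameter="a",
        z_rows=np.array([0.0]),
        pred_levels=np.array([0.0]),
        row_profiles=[prof],
        row_vpl=np.array([0.0]),
        row_widths=np.array([1.0]),
        criterion_W=1.0,
        validation=line_twod.validation,
        budget=0,
    )
    out = confidence_scale_export(twod)
    i = int(np.argmin(np.abs(prof.pl_values - chi2.ppf(0.95, 1))))
    assert out["param_conf"].iloc[i] == pytest.approx(
        chi2.cdf(prof.pl_values[i], 1), abs=1e-12
    )
    # symmetry of the exported row about the minimum
    conf = out["param_conf"].to_numpy()
    np.testing.assert_allclose(conf, conf[::-1], atol=1e-9)


def test_adding_own_prediction_never_widens_linear(line_setup):
    model, data, fit = line_setup["model"], line_setup["data"], line_setup["fit"]
    before = average_ci_width(profile_parameter(model, data, "a", fit=fit))
    cond = ExperimentalCondition("y", 5.0)
    zhat = float(fit.theta_hat @ np.array([5.0, 1.0]))
    aug = data.append(DataPoint(cond, zhat, line_setup["sigma"]))
    fit2 = fit_mle(model, aug, n_starts=1, seed=0, x0=fit.theta_hat)
    after = average_ci_width(profile_parameter(model, aug, "a", fit=fit2))
    assert after <= before + 1e-9


# --- sequential workflow -------------------------------------------------------


def test_sequential_stops_when_all_identifiable(line_setup):
    spec = line_setup["spec"]
    res = sequential_design(
        line_setup["model"],
        line_setup["data"],
        [ExperimentalCondition("y", 5.0)],
        fixtures.simulation_oracle(spec, seed=0),
        max_iter=3,
    )
    assert res.history == []
    assert res.stop_reason == "all_identifiable"
    assert len(res.dataset) == len(line_setup["data"])


def test_sequential_empty_candidates_reports_exhausted():
    # a single observation leaves the slope unidentifiable, but there is
    # nothing left to measure
    spec = fixtures.line_reference_spec(xs=(2.0,), seed=5)
    data = fixtures.simulate_dataset(spec, 5)
    res = sequential_design(
        spec.model, data, [], fixtures.simulation_oracle(spec, seed=0), max_iter=3
    )
    assert res.history == []
    assert res.stop_reason == "exhausted"


def test_sequential_abc_proposes_unobserved_state_first(abc_spec, abc_data):
    """Measuring A at t = 40 wins and renders p1 identifiable."""
    oracle = fixtures.simulation_oracle(abc_spec, seed=7)
    res = sequential_design(
        abc_spec.model,
        abc_data,
        fixtures.abc_candidates(),
        oracle,
        target_policy=["p1"],
        max_iter=1,
    )
    assert len(res.history) == 1
    step = res.history[0]
    assert step.target == "p1"
    assert step.measured.condition.observable == "A"
    assert step.measured.condition.time == 40.0
    fit2 = fit_mle(abc_spec.model, res.dataset, n_starts=10, seed=0)
    prof = profile_parameter(abc_spec.model, res.dataset, "p1", fit=fit2)
    from pl2design.profiles import IDENTIFIABLE, classify_identifiability

    assert classify_identifiability(prof) == IDENTIFIABLE
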