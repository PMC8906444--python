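"""Shared fixtures: the seeded ABC study, a linear-Gaussian reference, helpers.

The expensive ABC objects (multistart fit, all-parameter profiles, the
three-candidate design ranking) are session-scoped so the identifiability
and design tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from pl2design import fixtures
from pl2design.config import Config
from pl2design.design import select_design
from pl2design.estimation import fit_mle
from pl2design.profiles import ProfileCurve, profile_all_parameters


def make_quadratic_profile(
    s: float = 1.0,
    beta_hat: float = 0.0,
    lo: float = -10.0,
    hi: float = 10.0,
    span: float = 6.0,
    n: int = 1601,
    parameter: str = "beta",
) -> ProfileCurve:
    """Analytic quadratic profile PL(beta) = ((beta - beta_hat)/s)^2."""
    grid = np.linspace(beta_hat - span * s, beta_hat + span * s, n)
    return ProfileCurve(
        parameter=parameter,
        beta_grid=grid,
        pl_values=((grid - beta_hat) / s) ** 2,
        nuisance_at_beta=[None] * n,
        theta_hat_ref=np.array([beta_hat]),
        objective_ref=0.0,
        lower_bound=lo,
        upper_bound=hi,
    )


def make_flat_profile(lo=-5.0, hi=3.0, n=21, value=0.0) -> ProfileCurve:
    grid = np.linspace(lo, hi, n)
    return ProfileCurve(
        parameter="beta",
        beta_grid=grid,
        pl_values=np.full(n, value),
        nuisance_at_beta=[None] * n,
        theta_hat_ref=np.array([0.0]),
        objective_ref=0.0,
        lower_bound=lo,
        upper_bound=hi,
    )


@pytest.fixture(scope="session")
def abc_spec():
    return fixtures.abc_reference_spec(seed=1)


@pytest.fixture(scope="session")
def abc_data(abc_spec):
    return fixtures.simulate_dataset(abc_spec, seed=1)


@pytest.fixture(scope="session")
def abc_fit(abc_spec, abc_data):
    return fit_mle(abc_spec.model, abc_data, n_starts=20, seed=0)


@pytest.fixture(scope="session")
def abc_profiles(abc_spec, abc_data, abc_fit):
    return profile_all_parameters(abc_spec.model, abc_data, fit=abc_fit)


@pytest.fixture(scope="session")
def abc_ranking(abc_spec, abc_data, abc_fit):
    """Design ranking of the three t = 40 candidates targeting p1."""
    return select_design(
        abc_spec.model, abc_data, fixtures.abc_candidates(), "p1", fit=abc_fit
    )


@pytest.fixture(scope="session")
def line_setup():
    """Linear-Gaussian study with its closed-form least-squares quantities."""
    spec = fixtures.line_reference_spec(a=1.0, b=0.5, xs=(0.0, 1.0, 2.0, 3.0),
                                        sigma=0.1, seed=3)
    data = fixtures.simulate_dataset(spec, seed=3)
    fit = fit_mle(spec.model, data, n_starts=5, seed=0)
    X = np.column_stack([np.array([0.0, 1.0, 2.0, 3.0]), np.ones(4)])
    cov = spec.noise_sd_log**2 * np.linalg.inv(X.T @ X)
    return {
        "spec": spec,
        "model": spec.model,
        "data": data,
        "fit": fit,
        "X": X,
        "cov": cov,
        "sigma": spec.noise_sd_log,
        "s_a": float(np.sqrt(cov[0, 0])),
    }
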