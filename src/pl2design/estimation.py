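"""Likelihood evaluation and multistart maximum-likelihood estimation.

The objective is -2 ln L for independent Gaussian measurement errors,

    LL(theta) = sum_i (y_i - F_i(theta))^2 / sigma_i^2  [+ sum_i ln(2 pi sigma_i^2)]

where F_i is the model prediction on the data scale.  The additive
constant is included only when some sigma depends on parameters (otherwise
it shifts the objective uniformly and is dropped); the choice is global
and recorded in the fit result.

When all sigmas are parameter-free the problem is a bound-constrained
least-squares fit on the weighted residual vector (trust-region
reflective); with parametric sigmas a quasi-Newton minimizer runs on the
full objective.  Multistart draws start points from a scrambled Sobol
sequence inside the bounds; the sequence is prefix-stable, so enlarging
the start budget for a fixed seed can only improve the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .config import Config, DEFAULT
from .model import (
    Dataset,
    NumericalError,
    OdeModel,
    ValidationError,
    dataset_is_parametric_sigma,
    predict_conditions,
    resolve_sigma,
)

log = logging.getLogger(__name__)

# residual magnitude signalling an integration failure; far above any
# genuine weighted residual so misfit is never mistaken for failure
_PENALTY = 1e8
_PENALTY_OBJ = 1e15


class OptCounter:
    """Counts local optimizations (one per least-squares / minimize call)."""

    def __init__(self):
        self.n = 0

    def tick(self, k: int = 1) -> None:
        self.n += k


@dataclass
class FitResult:
    """Outcome of a (multistart) maximum-likelihood fit."""

    theta_hat: np.ndarray
    objective: float              # -2 ln L at the optimum
    n_starts: int
    converged_fraction: float     # fraction of starts within tol of the best
    start_seed: int
    constant_included: bool = False
    start_objectives: list = field(default_factory=list)
    n_opt: int = 0

    def to_dict(self, model: Optional[OdeModel] = None) -> dict:
        d = {
            "objective": float(self.objective),
            "n_starts": self.n_starts,
            "converged_fraction": float(self.converged_fraction),
            "start_seed": self.start_seed,
            "constant_included": self.constant_included,
            "n_opt": self.n_opt,
        }
        if model is not None:
            d["theta_hat"] = {
                name: float(v) for name, v in zip(model.parameter_names, self.theta_hat)
            }
        else:
            d["theta_hat"] = [float(v) for v in self.theta_hat]
        return d


def _sigmas(model: OdeModel, dataset: Dataset, theta) -> np.ndarray:
    return np.array([resolve_sigma(model, pt, theta) for pt in dataset], float)


def residuals(model: OdeModel, theta, dataset: Dataset, config: Config = DEFAULT) -> np.ndarray:
    """Weighted residual vector (y - F)/sigma; requires parameter-free sigmas."""
    preds = predict_conditions(model, theta, dataset.conditions(), config)
    sig = _sigmas(model, dataset, theta)
    return (dataset.values() - preds) / sig


def neg2_log_likelihood(
    model: OdeModel,
    theta,
    dataset: Dataset,
    config: Config = DEFAULT,
    include_constant: Optional[bool] = None,
) -> float:
    """-2 ln L; +inf (with a warning) when the simulation fails at theta."""
    theta = model.check_theta(theta)
    if include_constant is None:
        include_constant = dataset_is_parametric_sigma(model, dataset)
    if len(dataset) == 0:
        return 0.0
    try:
        preds = predict_conditions(model, theta, dataset.conditions(), config)
    except NumericalError as exc:
        log.warning("objective at theta failed (%s); returning +inf", exc)
        return np.inf
    sig = _sigmas(model, dataset, theta)
    value = float(np.sum(((dataset.values() - preds) / sig) ** 2))
    if include_constant:
        value += float(np.sum(np.log(2.0 * np.pi * sig**2)))
    return value


def _safe_residuals(model, dataset, config, fixed: Optional[tuple[int, float]]):
    """Residual closure over the free parameters; failures map to a finite penalty."""
    n = len(model.parameters)
    free = [i for i in range(n) if fixed is None or i != fixed[0]]

    def expand(x):
        theta = np.empty(n)
        theta[free] = x
        if fixed is not None:
            theta[fixed[0]] = fixed[1]
        return theta

    def fun(x):
        try:
            return residuals(model, expand(x), dataset, config)
        except NumericalError:
            return np.full(max(len(dataset), 1), _PENALTY)

    return fun, expand, free


def _local_least_squares(model, dataset, x0, config, fixed, counter):
    fun, expand, free = _safe_residuals(model, dataset, config, fixed)
    lo, hi = model.bounds()
    x0 = np.clip(np.asarray(x0, float)[free], lo[free], hi[free])
    if counter is not None:
        counter.tick()
    res = least_squares(
        fun,
        x0,
        bounds=(lo[free], hi[free]),
        method="trf",
        gtol=config.gtol,
        xtol=config.xtol,
        ftol=config.ftol,
    )
    theta = expand(res.x)
    obj = float(2.0 * res.cost)  # sum of squared weighted residuals
    if obj >= _PENALTY_OBJ:
        raise NumericalError("local fit stuck on an integration-failure plateau")
    return theta, obj


def _local_minimize(model, dataset, x0, config, fixed, counter):
    n = len(model.parameters)
    free = [i for i in range(n) if fixed is None or i != fixed[0]]
    lo, hi = model.bounds()

    def expand(x):
        theta = np.empty(n)
        theta[free] = x
        if fixed is not None:
            theta[fixed[0]] = fixed[1]
        return theta

    def fun(x):
        v = neg2_log_likelihood(model, expand(x), dataset, config, include_constant=True)
        return v if np.isfinite(v) else _PENALTY_OBJ

    if counter is not None:
        counter.tick()
    res = minimize(
        fun,
        np.clip(np.asarray(x0, float)[free], lo[free], hi[free]),
        method="L-BFGS-B",
        bounds=list(zip(lo[free], hi[free])),
        options={"gtol": config.gtol, "ftol": 1e-12},
    )
    if res.fun >= _PENALTY_OBJ:
        raise NumericalError("local fit stuck on an integration-failure plateau")
    return expand(res.x), float(res.fun)


def local_fit(
    model: OdeModel,
    dataset: Dataset,
    x0,
    config: Config = DEFAULT,
    fixed: Optional[tuple[int, float]] = None,
    counter: Optional[OptCounter] = None,
):
    """One deterministic local optimization from x0.

    ``fixed=(index, value)`` pins a single parameter (used by the
    profilers); returns the full parameter vector and -2 ln L.
    """
    if dataset_is_parametric_sigma(model, dataset):
        return _local_minimize(model, dataset, x0, config, fixed, counter)
    return _local_least_squares(model, dataset, x0, config, fixed, counter)


def fit_mle(
    model: OdeModel,
    dataset: Dataset,
    n_starts: Optional[int] = None,
    seed: Optional[int] = None,
    config: Config = DEFAULT,
    x0=None,
    counter: Optional[OptCounter] = None,
) -> FitResult:
    """Multistart MLE: best local optimum over Sobol-drawn start points.

    The first start is ``x0`` when given, else the model defaults; the
    remaining ``n_starts - 1`` points come from a scrambled Sobol sequence
    inside the bounds, reproducible for a fixed seed.
    """
    n_starts = config.n_starts if n_starts is None else int(n_starts)
    seed = config.seed if seed is None else int(seed)
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    lo, hi = model.bounds()
    starts = [np.asarray(x0, float) if x0 is not None else model.defaults()]
    if n_starts > 1:
        sob = qmc.Sobol(d=len(model.parameters), scramble=True, seed=seed)
        # draw a power-of-two batch and slice: the sequence is prefix-stable,
        # so a larger start budget extends (never reshuffles) the start set
        m = 1 << max(0, (n_starts - 2).bit_length())
        unit = sob.random(m)[: n_starts - 1]
        starts.extend(lo + unit * (hi - lo))

    counter = counter if counter is not None else OptCounter()
    best_theta, best_obj = None, np.inf
    objs, failures = [], []
    for i, s in enumerate(starts):
        try:
            theta, obj = local_fit(model, dataset, s, config, counter=counter)
        except NumericalError as exc:
            failures.append(f"start {i}: {exc}")
            objs.append(np.inf)
            continue
        objs.append(obj)
        if obj < best_obj:
            best_theta, best_obj = theta, obj
    if best_theta is None:
        raise NumericalError(
            "all starts failed: " + "; ".join(failures[:5])
            + ("..." if len(failures) > 5 else "")
        )
    converged = float(np.mean(np.abs(np.array(objs) - best_obj) < 1e-2))
    constant = dataset_is_parametric_sigma(model, dataset)
    return FitResult(
        theta_hat=best_theta,
        objective=best_obj,
        n_starts=n_starts,
        converged_fraction=converged,
        start_seed=seed,
        constant_included=constant,
        start_objectives=[float(o) for o in objs],
        n_opt=counter.n,
    )
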