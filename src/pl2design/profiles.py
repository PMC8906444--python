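"""Profile likelihoods, confidence intervals and the average-width summary.

A parameter profile fixes the parameter of interest at beta and
re-optimizes all nuisance parameters,

    PL(beta) = -2 ln [ L(beta, omega_hat(beta)) / L(theta_hat) ]  >= 0,

so that by Wilks' theorem { beta : PL(beta) < icdf(chi2_1, alpha) } is an
alpha-level confidence interval.  A validation profile applies the same
construction to a hypothetical measurement outcome z at a candidate
condition, by refitting all parameters on the dataset augmented with
(condition, z).

Profiles are sampled by an adaptive bidirectional walk from the optimum:
the step controller targets a fixed -2 log LR increment per step, halves
on overshoot, and stops once the curve has passed the 95% chi-square
threshold (plus a margin) or hit a parameter bound.  Each grid point's
re-optimization is warm-started from its neighbour, which is what keeps
the whole construction at a small number of cheap local fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.stats import chi2, qmc

from .config import Config, DEFAULT
from .estimation import FitResult, OptCounter, fit_mle, local_fit
from .model import (
    Dataset,
    DataPoint,
    ExperimentalCondition,
    NumericalError,
    OdeModel,
    ValidationError,
    predict_observable,
    resolve_sigma,
)

log = logging.getLogger(__name__)

IDENTIFIABLE = "identifiable"
PRACTICALLY_NON_IDENTIFIABLE = "practically_non_identifiable"
STRUCTURALLY_NON_IDENTIFIABLE = "structurally_non_identifiable"


def threshold(level: float, df: int = 1) -> float:
    """-2 log LR confidence threshold: icdf(chi2_df, level)."""
    return float(chi2.ppf(level, df))


@dataclass
class ProfileCurve:
    """Sampled profile likelihood for one parameter."""

    parameter: str
    beta_grid: np.ndarray          # ascending, on the parameter's scale
    pl_values: np.ndarray          # -2 log ratio to the reference optimum, >= 0
    nuisance_at_beta: list         # full parameter vector per grid point
    theta_hat_ref: np.ndarray
    objective_ref: float
    lower_bound: float
    upper_bound: float
    bounds_hit: tuple[bool, bool] = (False, False)  # side reached bound below threshold
    level: float = 0.95
    n_opt: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.beta_grid.size

    @property
    def beta_hat(self) -> float:
        return float(self.beta_grid[int(np.argmin(self.pl_values))])


@dataclass(frozen=True)
class ConfidenceInterval:
    level: float
    lower: float
    upper: float
    lower_open: bool = False   # profile did not cross before the bound
    upper_open: bool = False

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class IdentifiabilityStatus:
    status: str
    level: float = 0.95

    def __eq__(self, other):
        if isinstance(other, str):
            return self.status == other
        return (self.status, self.level) == (other.status, other.level)


@dataclass
class ValidationProfile:
    """Profile over the outcome z of a not-yet-measured condition."""

    condition: ExperimentalCondition
    z_grid: np.ndarray
    vpl_values: np.ndarray         # includes the weak prior when regularized
    theta_at_z: list
    z_hat: float
    sigma_z: float
    objective_ref: float
    crossed: tuple[bool, bool] = (True, True)
    regularized: bool = False
    reg_lambda: float = 0.0
    reg_scale: float = 0.0
    n_opt: int = 0
    meta: dict = field(default_factory=dict)


# --- adaptive stepper -----------------------------------------------------------


def _walk(
    evalf: Callable,
    x0: float,
    pl0: float,
    warm0,
    direction: int,
    bound: float,
    thr: float,
    cfg: Config,
    span: float,
):
    """Walk from (x0, pl0) toward ``bound``; returns (points, reached_bound_open).

    ``evalf(x, warm) -> (pl, payload)``.  Points are (x, pl, payload) in walk
    order.  ``reached_bound_open`` is True when the walk arrived at the bound
    with the profile still below the threshold (an open CI side).
    """
    target = cfg.target_dpl_frac * thr
    stop_pl = thr + cfg.margin
    min_step = cfg.min_step_frac * span
    max_step = cfg.max_step_frac * span
    step = cfg.initial_step_frac * span
    x, pl, warm = x0, pl0, warm0
    pts, drops = [], 0
    open_side = np.isfinite(bound) and direction * (bound - x0) <= 0
    for _ in range(cfg.max_steps_per_side):
        x_new = x + direction * step
        at_bound = False
        if np.isfinite(bound) and direction * (x_new - bound) >= 0:
            x_new = bound
            at_bound = True
        try:
            pl_new, payload = evalf(x_new, warm)
        except NumericalError:
            drops += 1
            if drops > cfg.drop_tolerance * cfg.max_steps_per_side:
                raise NumericalError(
                    f"too many failed profile points ({drops})"
                ) from None
            if step > 4 * min_step and not at_bound:
                step /= 2.0          # retreat: maybe a gentler step integrates
            else:
                x = x_new            # step over the bad region
            continue
        dpl = abs(pl_new - pl)
        if dpl > 4.0 * target and step > 2 * min_step and not at_bound:
            step = max(step / 2.0, min_step)
            continue
        pts.append((x_new, pl_new, payload))
        x, pl, warm = x_new, pl_new, payload
        if pl_new > stop_pl:
            open_side = False
            break
        if at_bound:
            open_side = pl_new <= thr
            break
        step = float(
            np.clip(step * np.clip(target / max(dpl, 1e-12), 0.5, 2.0), min_step, max_step)
        )
    else:
        # walk exhausted without crossing or reaching the bound
        open_side = True
    return pts, open_side, drops


def _assemble(center_x, center_pl, center_payload, left_pts, right_pts):
    xs = [p[0] for p in reversed(left_pts)] + [center_x] + [p[0] for p in right_pts]
    pls = [p[1] for p in reversed(left_pts)] + [center_pl] + [p[1] for p in right_pts]
    pays = [p[2] for p in reversed(left_pts)] + [center_payload] + [p[2] for p in right_pts]
    order = np.argsort(xs, kind="stable")
    xs = np.array(xs, float)[order]
    pls = np.array(pls, float)[order]
    pays = [pays[i] for i in order]
    return xs, pls, pays


# --- parameter profiles ---------------------------------------------------------


def profile_parameter(
    model: OdeModel,
    dataset: Dataset,
    parameter: str,
    config: Config = DEFAULT,
    fit: Optional[FitResult] = None,
    counter: Optional[OptCounter] = None,
) -> ProfileCurve:
    """Profile likelihood of one parameter by adaptive bidirectional stepping."""
    counter = counter if counter is not None else OptCounter()
    if fit is None:
        fit = fit_mle(model, dataset, config=config, counter=counter)
    idx = model.index(parameter)
    pdef = model.parameter(parameter)
    beta_hat = float(fit.theta_hat[idx])
    ref_obj = fit.objective
    thr = threshold(config.level)

    def evalf(beta, warm):
        theta, obj = local_fit(
            model, dataset, warm, config, fixed=(idx, beta), counter=counter
        )
        return obj - ref_obj, theta

    n0 = counter.n
    left, open_left, d1 = _walk(
        evalf, beta_hat, 0.0, fit.theta_hat, -1, pdef.lower_bound, thr, config,
        span=pdef.upper_bound - pdef.lower_bound,
    )
    right, open_right, d2 = _walk(
        evalf, beta_hat, 0.0, fit.theta_hat, +1, pdef.upper_bound, thr, config,
        span=pdef.upper_bound - pdef.lower_bound,
    )
    grid, pls, pays = _assemble(beta_hat, 0.0, fit.theta_hat, left, right)

    # profiling may stumble on a better optimum than the multistart fit;
    # re-anchor so the curve's minimum is exactly zero
    shift = float(pls.min())
    if shift < -1e-6:
        log.warning(
            "profile of %s found an optimum %.3g below the fit; re-anchoring",
            parameter, -shift,
        )
    pls = np.maximum(pls - min(shift, 0.0), 0.0)
    return ProfileCurve(
        parameter=parameter,
        beta_grid=grid,
        pl_values=pls,
        nuisance_at_beta=pays,
        theta_hat_ref=fit.theta_hat,
        objective_ref=ref_obj + min(shift, 0.0),
        lower_bound=pdef.lower_bound,
        upper_bound=pdef.upper_bound,
        bounds_hit=(open_left, open_right),
        level=config.level,
        n_opt=counter.n - n0,
        meta={"dropped_points": d1 + d2, "re_anchored": shift < -1e-6},
    )


def _cross(grid, pls, thr, i_min, direction):
    """Threshold crossing on one side of the minimum.

    Interpolates linearly in sqrt(PL), which is exact when the profile is
    locally quadratic (sqrt of a parabola is piecewise linear in beta) and
    avoids the systematic inward bias of linear-in-PL interpolation on the
    coarse part of the grid near the minimum.
    """
    idxs = range(i_min, -1, -1) if direction < 0 else range(i_min, len(grid))
    prev = None
    for j in idxs:
        if prev is not None and pls[j] >= thr > pls[prev]:
            x0, x1 = grid[prev], grid[j]
            y0, y1 = np.sqrt(pls[prev]), np.sqrt(pls[j])
            t = np.sqrt(thr)
            if y1 == y0:
                return float(x1)
            return float(x0 + (t - y0) / (y1 - y0) * (x1 - x0))
        prev = j
    return None


def confidence_interval(profile: ProfileCurve, level: float) -> ConfidenceInterval:
    """CI from the profile: endpoints where PL crosses icdf(chi2_1, level).

    Sides without a crossing are clipped to the parameter bound and flagged
    open; level 0 gives the degenerate interval at the profile minimum.
    """
    if not 0 <= level <= 1:
        raise ValidationError("confidence level must be in [0, 1]")
    if len(profile) < 3:
        raise ValidationError("profile has fewer than 3 points")
    grid, pls = profile.beta_grid, profile.pl_values
    i_min = int(np.argmin(pls))
    if level <= 0:
        b = float(grid[i_min])
        return ConfidenceInterval(level, b, b)
    if level >= 1:
        # infinite threshold: nothing is excluded within the bounds
        return ConfidenceInterval(
            level, profile.lower_bound, profile.upper_bound, True, True
        )
    thr = threshold(level)
    lower = _cross(grid, pls, thr, i_min, -1)
    upper = _cross(grid, pls, thr, i_min, +1)
    lower_open = lower is None
    upper_open = upper is None
    return ConfidenceInterval(
        level,
        profile.lower_bound if lower is None else lower,
        profile.upper_bound if upper is None else upper,
        lower_open,
        upper_open,
    )


def classify_identifiability(
    profile: ProfileCurve, level: float = 0.95
) -> IdentifiabilityStatus:
    """identifiable / practically / structurally non-identifiable at ``level``.

    Identifiable: the profile crosses the threshold on both sides.  A flat
    profile (max below 5% of the threshold) is structurally non-identifiable;
    anything in between is practically non-identifiable.
    """
    thr = threshold(level)
    ci = confidence_interval(profile, level)
    if not ci.lower_open and not ci.upper_open:
        return IdentifiabilityStatus(IDENTIFIABLE, level)
    if float(np.max(profile.pl_values)) < 0.05 * thr:
        return IdentifiabilityStatus(STRUCTURALLY_NON_IDENTIFIABLE, level)
    return IdentifiabilityStatus(PRACTICALLY_NON_IDENTIFIABLE, level)


def average_ci_width(
    profile: ProfileCurve,
    alpha_max: float = 0.95,
    n_alpha: int = 50,
) -> float:
    """Average confidence-interval width, integral of w(CI_alpha) d alpha.

    Trapezoidal quadrature on an equispaced alpha grid over [0, alpha_max];
    the integral is NOT renormalized by alpha_max (a monotone transform that
    leaves design rankings unchanged).  Open sides contribute their
    bounds-clipped width, which is what makes the summary penalize designs
    that leave the parameter non-identifiable.
    """
    alphas = np.linspace(0.0, alpha_max, n_alpha)
    widths = np.array([confidence_interval(profile, a).width for a in alphas])
    return float(np.trapezoid(widths, alphas))


# --- validation (prediction) profiles -------------------------------------------


def prediction_span(
    model: OdeModel,
    condition: ExperimentalCondition,
    config: Config = DEFAULT,
    n_sample: int = 64,
    seed: int = 0,
) -> float:
    """Robust span of the prediction over the parameter-bounds box.

    Used as the scale R of the weak quadratic prior for unbounded
    predictions; estimated from a Sobol sample of the box (non-finite and
    failed predictions are discarded, the 2.5-97.5 percentile span is used).
    """
    lo, hi = model.bounds()
    unit = qmc.Sobol(d=lo.size, scramble=True, seed=seed).random(n_sample)
    obs = model.observable(condition.observable)
    vals = []
    for row in lo + unit * (hi - lo):
        try:
            v = predict_observable(model, row, condition, config)
        except NumericalError:
            continue
        if np.isfinite(v):
            if obs.outcome_bounds is not None:
                v = float(np.clip(v, *obs.outcome_bounds))
            vals.append(v)
    if len(vals) < 8:
        return 1.0
    lo_q, hi_q = np.percentile(vals, [2.5, 97.5])
    return float(max(hi_q - lo_q, 1e-3))


def validation_profile(
    model: OdeModel,
    dataset: Dataset,
    condition: ExperimentalCondition,
    config: Config = DEFAULT,
    fit: Optional[FitResult] = None,
    sigma_z: Optional[float] = None,
    counter: Optional[OptCounter] = None,
) -> ValidationProfile:
    """Profile over the hypothetical outcome z of measuring ``condition``.

    For each z the full parameter vector is refit on the dataset augmented
    with (condition, z, sigma_z), warm-started from the neighbouring grid
    point.  The curve is anchored so VPL(z_hat) = 0 at the current
    prediction z_hat.  If a side fails to cross the 95% threshold within
    the step budget (a practically non-identifiable prediction), a weak
    quadratic prior lambda * ((z - z_hat)/R)^2 is added and the walk
    continues; the result is flagged ``regularized``.
    """
    counter = counter if counter is not None else OptCounter()
    if fit is None:
        fit = fit_mle(model, dataset, config=config, counter=counter)
    obs = model.observable(condition.observable)
    z_lo, z_hi = obs.outcome_bounds if obs.outcome_bounds is not None else (-np.inf, np.inf)
    z_hat = predict_observable(model, fit.theta_hat, condition, config)
    z_hat = float(np.clip(z_hat, z_lo, z_hi))
    if sigma_z is None:
        probe = DataPoint(condition, z_hat, None)
        sigma_z = resolve_sigma(model, probe, fit.theta_hat)
    ref_obj = fit.objective
    thr = threshold(config.level)
    span = max(10.0 * sigma_z, 1e-6)

    prior = {"lam": 0.0, "scale": 1.0}

    def evalf(z, warm):
        aug = dataset.append(DataPoint(condition, z, sigma_z))
        theta, obj = local_fit(model, aug, warm, config, counter=counter)
        pen = prior["lam"] * ((z - z_hat) / prior["scale"]) ** 2
        return max(obj - ref_obj, 0.0) + pen, theta

    def walk_side(direction, walk_span):
        return _walk(
            evalf, z_hat, 0.0, fit.theta_hat, direction,
            z_hi if direction > 0 else z_lo,
            thr, config, span=walk_span,
        )

    n0 = counter.n
    left, open_left, d1 = walk_side(-1, span)
    right, open_right, d2 = walk_side(+1, span)
    regularized = False
    if open_left or open_right:
        # unbounded prediction: add the weak prior and re-walk the open sides,
        # with the step scale widened to the prior's scale R so the walk can
        # actually reach the prior-induced crossing
        regularized = True
        prior["lam"] = config.reg_lambda
        prior["scale"] = prediction_span(model, condition, config, seed=config.seed)
        reg_span = max(span, prior["scale"])
        if open_left:
            left, open_left, _ = walk_side(-1, reg_span)
        if open_right:
            right, open_right, _ = walk_side(+1, reg_span)

    grid, pls, pays = _assemble(z_hat, 0.0, fit.theta_hat, left, right)
    return ValidationProfile(
        condition=condition,
        z_grid=grid,
        vpl_values=pls,
        theta_at_z=pays,
        z_hat=z_hat,
        sigma_z=float(sigma_z),
        objective_ref=ref_obj,
        crossed=(not open_left, not open_right),
        regularized=regularized,
        reg_lambda=prior["lam"],
        reg_scale=prior["scale"] if regularized else 0.0,
        n_opt=counter.n - n0,
        meta={"dropped_points": d1 + d2},
    )


def profile_all_parameters(
    model: OdeModel,
    dataset: Dataset,
    config: Config = DEFAULT,
    fit: Optional[FitResult] = None,
    counter: Optional[OptCounter] = None,
) -> dict[str, ProfileCurve]:
    """Profiles for every model parameter (the per-iteration workflow step)."""
    counter = counter if counter is not None else OptCounter()
    if fit is None:
        fit = fit_mle(model, dataset, config=config, counter=counter)
    return {
        name: profile_parameter(model, dataset, name, config, fit=fit, counter=counter)
        for name in model.parameter_names
    }
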