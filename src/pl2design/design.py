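"""Two-dimensional likelihood profiles and the expected-width design criterion.

For a candidate condition D and target parameter, the two-dimensional
profile combines the validation profile over hypothetical outcomes z with
the parameter profile recomputed on the augmented dataset Y u {z}:

    PL2D(z, beta) = PL(beta | Y u {z}) + VPL(z),

an algebraic identity because all three ratios share the denominator
L(theta_hat(Y) | Y, z_hat).  Outcome rows are placed at equidistant
two-sided predictive-confidence quantiles derived from the validation
profile, truncated at the 95% predictive level; with that placement the
predictive-density-weighted integral of the per-outcome average CI widths
reduces to their unweighted mean, which is the design criterion W.  The
best candidate is the one minimizing W.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .config import Config, DEFAULT
from .estimation import FitResult, OptCounter, fit_mle, local_fit
from .model import (
    DataPoint,
    Dataset,
    ExperimentalCondition,
    NumericalError,
    OdeModel,
    ValidationError,
)
from .profiles import (
    IDENTIFIABLE,
    ProfileCurve,
    ValidationProfile,
    average_ci_width,
    classify_identifiability,
    confidence_interval,
    profile_all_parameters,
    profile_parameter,
    validation_profile,
)

log = logging.getLogger(__name__)


@dataclass
class DesignRegion:
    """Finite list of candidate experimental conditions."""

    candidates: list[ExperimentalCondition]

    def __len__(self):
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


@dataclass
class TwoDProfile:
    """Outcome-row by parameter-column profile grid for one candidate."""

    condition: ExperimentalCondition
    target_parameter: str
    z_rows: np.ndarray             # outcome value per surviving row
    pred_levels: np.ndarray        # signed two-sided predictive confidence per row
    row_profiles: list[ProfileCurve]   # target profile on Y u {z}, one per row
    row_vpl: np.ndarray            # VPL(z) per row (shared denominator)
    row_widths: np.ndarray         # average CI width of the target per row
    criterion_W: float
    validation: ValidationProfile
    budget: int                    # local optimizations spent on this profile
    flagged: bool = False          # > drop_tolerance of rows failed
    n_rows_dropped: int = 0

    def pl2d_row(self, i: int) -> np.ndarray:
        """PL2D values along row i (adds the row's VPL to its profile)."""
        return self.row_profiles[i].pl_values + self.row_vpl[i]


@dataclass
class DesignRanking:
    """Candidates ordered by ascending expected average width."""

    entries: list[tuple[ExperimentalCondition, float]]
    selected: ExperimentalCondition
    tie_note: str = ""
    profiles_2d: dict = field(default_factory=dict)   # condition -> TwoDProfile
    failures: dict = field(default_factory=dict)      # condition -> error message


def _branch_reach(vp: ValidationProfile, direction: int) -> float:
    """Predictive confidence reachable on one side of z_hat (<= 1)."""
    grid, pls = vp.z_grid, vp.vpl_values
    i_hat = int(np.argmin(np.abs(grid - vp.z_hat)))
    ys = pls[: i_hat + 1] if direction < 0 else pls[i_hat:]
    if ys.size == 0:
        return 0.0
    return float(chi2.cdf(np.max(ys), 1))


def _branch_quantile(vp: ValidationProfile, level: float) -> float:
    """Outcome z at signed two-sided predictive confidence ``level``.

    Predictive CDF via equal-tail allocation: F(z) = (1 - C(z))/2 left of
    z_hat and (1 + C(z))/2 right of it, with C(z) = cdf(chi2_1, VPL(z)).
    ``level`` < 0 addresses the left branch, > 0 the right.
    """
    if abs(level) < 1e-12:
        return vp.z_hat
    v_target = float(chi2.ppf(abs(level), 1))
    grid, pls = vp.z_grid, vp.vpl_values
    i_hat = int(np.argmin(np.abs(grid - vp.z_hat)))
    if level < 0:
        xs = grid[: i_hat + 1][::-1]
        ys = pls[: i_hat + 1][::-1]
    else:
        xs = grid[i_hat:]
        ys = pls[i_hat:]
    ys = np.maximum.accumulate(ys)  # enforce monotone away from z_hat
    if v_target > ys[-1]:
        return float(xs[-1])
    j = int(np.searchsorted(ys, v_target))
    if j == 0:
        return float(xs[0])
    y0, y1 = ys[j - 1], ys[j]
    frac = 0.0 if y1 == y0 else (v_target - y0) / (y1 - y0)
    return float(xs[j - 1] + frac * (xs[j] - xs[j - 1]))


def profile_2d(
    model: OdeModel,
    dataset: Dataset,
    condition: ExperimentalCondition,
    target_parameter: str,
    config: Config = DEFAULT,
    fit: Optional[FitResult] = None,
) -> TwoDProfile:
    """Two-dimensional likelihood profile for one candidate condition.

    Rows are outcome values at ``n_z_rows`` equidistant predictive
    quantiles over the reachable confidence range per side (capped at
    ``pred_cap``); each row refits the model on the augmented dataset and
    profiles the target parameter, warm-started across rows.
    """
    counter = OptCounter()
    if fit is None:
        fit = fit_mle(model, dataset, config=config, counter=counter)
    model.index(target_parameter)  # validate
    vp = validation_profile(model, dataset, condition, config, fit=fit, counter=counter)

    # rows span the reachable predictive confidence per side: when the
    # outcome space is truncated (assay range), the quantile grid conditions
    # on the measurable range instead of stacking rows at the bound
    c_left = min(config.pred_cap, _branch_reach(vp, -1))
    c_right = min(config.pred_cap, _branch_reach(vp, +1))
    levels = np.linspace(-c_left, c_right, config.n_z_rows)
    zs = np.array([_branch_quantile(vp, c) for c in levels])

    rows_z, rows_lvl, rows_prof, rows_vpl, rows_w = [], [], [], [], []
    dropped = 0
    warm = None
    for z, lvl in zip(zs, levels):
        if rows_z and abs(z - rows_z[-1]) < 1e-12:
            # quantile truncated at the outcome bound: identical row, reuse it
            rows_z.append(float(z))
            rows_lvl.append(float(lvl))
            rows_prof.append(rows_prof[-1])
            rows_vpl.append(rows_vpl[-1])
            rows_w.append(rows_w[-1])
            continue
        aug = dataset.append(DataPoint(condition, float(z), vp.sigma_z))
        # warm starts: previous row's solution and the VPL solution nearest z;
        # keep the better refit (rows can hop between local optima)
        i_near = int(np.argmin(np.abs(vp.z_grid - z)))
        starts = [vp.theta_at_z[i_near]] if warm is None else [warm, vp.theta_at_z[i_near]]
        try:
            fits = [local_fit(model, aug, s, config, counter=counter) for s in starts]
            theta_row, obj_row = min(fits, key=lambda f: f[1])
            row_fit = FitResult(
                theta_hat=theta_row, objective=obj_row, n_starts=1,
                converged_fraction=1.0, start_seed=config.seed,
            )
            prof = profile_parameter(
                model, aug, target_parameter, config, fit=row_fit, counter=counter
            )
        except NumericalError as exc:
            log.warning("2D profile row at z=%.4g dropped: %s", z, exc)
            dropped += 1
            warm = None
            continue
        warm = theta_row
        rows_z.append(float(z))
        rows_lvl.append(float(lvl))
        rows_prof.append(prof)
        # the profile may have re-anchored below the warm-started row fit;
        # use its reference objective so PL2D = PL(.|Y u z) + VPL(z) exactly
        rows_vpl.append(max(prof.objective_ref - fit.objective, 0.0))
        rows_w.append(average_ci_width(prof, config.alpha_max, config.n_alpha))
    if not rows_z:
        raise NumericalError(f"all rows failed for candidate {condition.label()}")
    flagged = dropped > config.drop_tolerance * config.n_z_rows
    return TwoDProfile(
        condition=condition,
        target_parameter=target_parameter,
        z_rows=np.array(rows_z),
        pred_levels=np.array(rows_lvl),
        row_profiles=rows_prof,
        row_vpl=np.array(rows_vpl),
        row_widths=np.array(rows_w),
        criterion_W=float(np.mean(rows_w)),
        validation=vp,
        budget=counter.n,
        flagged=flagged,
        n_rows_dropped=dropped,
    )


def expected_average_width(twod: TwoDProfile) -> float:
    """Design criterion W: expected average profile width over outcomes.

    With rows at equidistant predictive-confidence quantiles the
    predictive-density-weighted integral reduces to the unweighted mean of
    the per-row average widths.
    """
    if len(twod.row_widths) < 3:
        raise ValidationError("2D profile has fewer than 3 surviving rows")
    return float(np.mean(twod.row_widths))


def confidence_scale_export(twod: TwoDProfile) -> pd.DataFrame:
    """Tidy grid (pred_level, z, beta, param_conf) on the confidence scale.

    Each row's minimum is shifted to zero and -2 log LR values are mapped
    to confidence levels via cdf(chi2_1, .); rows are keyed by their signed
    two-sided predictive confidence.
    """
    frames = []
    for i in range(len(twod.z_rows)):
        pl2d = twod.pl2d_row(i)
        shifted = pl2d - pl2d.min()
        frames.append(
            pd.DataFrame(
                {
                    "pred_level": twod.pred_levels[i],
                    "z": twod.z_rows[i],
                    "beta": twod.row_profiles[i].beta_grid,
                    "param_conf": chi2.cdf(shifted, 1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _tie_order(entries, eps=1e-9):
    """Ascending by W; near-ties broken by earlier time, then input order."""
    order = sorted(range(len(entries)), key=lambda i: entries[i][1])
    note = []
    i = 0
    while i < len(order):
        j = i
        while (
            j + 1 < len(order)
            and abs(entries[order[j + 1]][1] - entries[order[i]][1]) < eps
        ):
            j += 1
        if j > i:
            group = sorted(order[i : j + 1], key=lambda k: (entries[k][0].time, k))
            order[i : j + 1] = group
            note.append(
                "tie among " + ", ".join(entries[k][0].label() for k in group)
                + " broken by earliest time, then list order"
            )
        i = j + 1
    return order, "; ".join(note)


def select_design(
    model: OdeModel,
    dataset: Dataset,
    candidates: DesignRegion | Sequence[ExperimentalCondition],
    target_parameter: str,
    config: Config = DEFAULT,
    fit: Optional[FitResult] = None,
) -> DesignRanking:
    """Rank candidates by the expected average width of the target's profile."""
    cands = list(candidates)
    if not cands:
        raise ValidationError("no candidate conditions given")
    if fit is None:
        fit = fit_mle(model, dataset, config=config)
    entries, profiles, failures = [], {}, {}
    for cond in cands:
        try:
            twod = profile_2d(model, dataset, cond, target_parameter, config, fit=fit)
        except NumericalError as exc:
            failures[cond] = str(exc)
            continue
        profiles[cond] = twod
        entries.append((cond, expected_average_width(twod)))
    if not entries:
        raise NumericalError(
            "all candidates failed: "
            + "; ".join(f"{c.label()}: {m}" for c, m in failures.items())
        )
    order, note = _tie_order(entries)
    ordered = [entries[i] for i in order]
    return DesignRanking(
        entries=ordered,
        selected=ordered[0][0],
        tie_note=note,
        profiles_2d=profiles,
        failures=failures,
    )


# --- sequential workflow --------------------------------------------------------


@dataclass
class DesignIteration:
    iteration: int
    fit: FitResult
    statuses: dict                 # parameter -> status string
    avg_widths: dict               # parameter -> average CI width
    target: Optional[str] = None
    ranking: Optional[DesignRanking] = None
    measured: Optional[DataPoint] = None


@dataclass
class SequentialResult:
    history: list[DesignIteration]
    dataset: Dataset
    stop_reason: str


def _candidate_hopeless(twod: TwoDProfile, level: float = 0.95) -> bool:
    """True when no sampled outcome row yields a both-sides-closed CI."""
    for prof in twod.row_profiles:
        ci = confidence_interval(prof, level)
        if not ci.lower_open and not ci.upper_open:
            return False
    return True


def sequential_design(
    model: OdeModel,
    dataset: Dataset,
    candidates: DesignRegion | Sequence[ExperimentalCondition],
    measurement_oracle: Callable[[ExperimentalCondition], float],
    target_policy: Optional[Sequence[str]] = None,
    max_iter: int = 10,
    config: Config = DEFAULT,
) -> SequentialResult:
    """Sequential loop: fit, profile, rank candidates, measure the best.

    Per iteration the model is refit, every parameter profiled and
    classified, a target chosen (first non-identifiable name from
    ``target_policy``, else the non-identifiable parameter with the widest
    average CI), candidates ranked by the design criterion, and the oracle
    queried for the winning condition; the new point joins the dataset and
    the condition leaves the candidate list.  Stops when no parameter is
    non-identifiable, candidates are exhausted, the iteration budget is
    spent, or no remaining candidate can make the target identifiable for
    any sampled outcome.
    """
    remaining = list(candidates)
    data = dataset
    history: list[DesignIteration] = []
    stop_reason = "max_iter"
    for it in range(max_iter):
        fit = fit_mle(model, data, config=config)
        profs = profile_all_parameters(model, data, config, fit=fit)
        statuses = {
            name: classify_identifiability(p, config.level).status
            for name, p in profs.items()
        }
        widths = {
            name: average_ci_width(p, config.alpha_max, config.n_alpha)
            for name, p in profs.items()
        }
        record = DesignIteration(it, fit, statuses, widths)
        nonident = [n for n, s in statuses.items() if s != IDENTIFIABLE]
        if not nonident:
            stop_reason = "all_identifiable"
            if it > 0:
                history.append(record)
            break
        target = None
        for name in target_policy or []:
            if name in nonident:
                target = name
                break
        if target is None:
            target = max(nonident, key=lambda n: widths[n])
        record.target = target
        if not remaining:
            stop_reason = "exhausted"
            if it > 0:
                history.append(record)
            break
        try:
            ranking = select_design(model, data, remaining, target, config, fit=fit)
        except NumericalError:
            history.append(record)
            stop_reason = "design_failed"
            break
        record.ranking = ranking
        if all(
            _candidate_hopeless(ranking.profiles_2d[c], config.level)
            for c, _ in ranking.entries
        ):
            stop_reason = "uninformative_candidates"
            history.append(record)
            break
        best = ranking.selected
        try:
            value = float(measurement_oracle(best))
        except Exception as exc:
            record.measured = None
            history.append(record)
            return SequentialResult(history, data, f"oracle_failed: {exc}")
        point = DataPoint(best, value, None)
        record.measured = point
        data = data.append(point)
        remaining = [c for c in remaining if c != best]
        history.append(record)
    return SequentialResult(history, data, stop_reason)
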