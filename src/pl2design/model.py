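"""ODE model container, simulation and dataset handling.

A model couples a right-hand side ``f(t, x, p, u)`` with parameter
metadata, observation functions and an error model.  Parameters declared
with ``scale="log10"`` are stored, bounded, optimized and profiled on the
log10 axis (the convention for rate constants, whose plausible ranges span
orders of magnitude); they are transformed to linear scale only when the
dynamics are evaluated.

Observables map the state vector to a measurable quantity; with
``data_scale="log10"`` both data and predictions live on the log10 axis,
which turns multiplicative (log-normal) measurement noise into additive
Gaussian noise with the stated standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import Config, DEFAULT

PARAM_ROLES = ("dynamic", "initial", "observation", "error")
SCALES = ("log10", "linear")


class ValidationError(ValueError):
    """Invalid user input: unknown names, malformed files, out-of-bounds values."""


class NumericalError(RuntimeError):
    """A numerical stage failed (integration blow-up, optimization failure)."""


class IntegrationError(NumericalError):
    """ODE integration failed; carries the offending parameter vector."""

    def __init__(self, message: str, theta=None):
        super().__init__(message)
        self.theta = None if theta is None else np.asarray(theta, float)


@dataclass(frozen=True)
class ParameterDef:
    """One model parameter: bounds, default and role, on its stated scale."""

    name: str
    role: str = "dynamic"
    scale: str = "log10"
    lower_bound: float = -5.0
    upper_bound: float = 3.0
    default: float = 0.0

    def __post_init__(self):
        if self.role not in PARAM_ROLES:
            raise ValidationError(f"parameter {self.name}: unknown role {self.role!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"parameter {self.name}: unknown scale {self.scale!r}")
        if not self.lower_bound < self.upper_bound:
            raise ValidationError(
                f"parameter {self.name}: lower_bound must be < upper_bound"
            )
        if not self.lower_bound <= self.default <= self.upper_bound:
            raise ValidationError(f"parameter {self.name}: default outside bounds")

    def to_linear(self, value: float) -> float:
        return 10.0 ** value if self.scale == "log10" else value


@dataclass(frozen=True)
class ObservableDef:
    """Observation function and error model for one measurable quantity.

    ``mapping(x, p)`` receives dicts of state and parameter values on linear
    scale and returns the observable on linear scale.  ``sigma`` is the
    measurement standard deviation *on the data scale*: a constant, the name
    of an error-role parameter, or a callable ``sigma(x, p)``.
    """

    name: str
    mapping: Callable[[dict, dict], float]
    data_scale: str = "log10"
    sigma: float | str | Callable = 0.2
    #: measurable range of the assay on the data scale (None: unbounded);
    #: hypothetical outcomes outside this range are never considered
    outcome_bounds: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.data_scale not in SCALES:
            raise ValidationError(f"observable {self.name}: unknown data_scale")
        if isinstance(self.sigma, (int, float)) and self.sigma <= 0:
            raise ValidationError(f"observable {self.name}: sigma must be positive")
        if self.outcome_bounds is not None and not (
            self.outcome_bounds[0] < self.outcome_bounds[1]
        ):
            raise ValidationError(f"observable {self.name}: bad outcome_bounds")

    @property
    def sigma_is_parametric(self) -> bool:
        return isinstance(self.sigma, str)


@dataclass(frozen=True)
class ExperimentalCondition:
    """A design point: the triple (observable, time, perturbation)."""

    observable: str
    time: float
    perturbation: str = "default"

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(f"negative time {self.time} for {self.observable}")

    def label(self) -> str:
        return f"{self.observable}@t={self.time:g}/{self.perturbation}"


@dataclass(frozen=True)
class DataPoint:
    """A measured value on the observable's data scale.

    ``sigma`` overrides the model's error model when given (a known
    measurement standard deviation); ``None`` defers to the error model.
    """

    condition: ExperimentalCondition
    value: float
    sigma: Optional[float] = None


@dataclass
class Dataset:
    """Ordered collection of data points (the likelihood is order-invariant)."""

    points: list[DataPoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def append(self, point: DataPoint) -> "Dataset":
        """Return a new dataset with ``point`` appended (non-mutating)."""
        return Dataset(self.points + [point])

    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points], float)

    def conditions(self) -> list[ExperimentalCondition]:
        return [p.condition for p in self.points]

    def observables(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.points:
            seen.setdefault(p.condition.observable, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observable": [p.condition.observable for p in self.points],
                "time": [p.condition.time for p in self.points],
                "perturbation": [p.condition.perturbation for p in self.points],
                "value": [p.value for p in self.points],
                "sigma": [p.sigma for p in self.points],
            }
        )


@dataclass
class OdeModel:
    """States, dynamics, observation model and parameter metadata.

    ``rhs(t, x, p, u)`` returns the state derivatives; ``x`` is the state
    vector, ``p`` a dict of parameter values on linear scale, ``u`` the
    resolved perturbation.  ``initial_values`` holds one entry per state,
    either a number (known initial condition) or a parameter name.
    ``solution(p, u, times)``, when provided, is a closed-form trajectory
    used in place of numerical integration (and cross-checked against the
    integrator in the test suite).
    """

    name: str
    state_names: list[str]
    rhs: Callable
    initial_values: Sequence
    observables: list[ObservableDef]
    parameters: list[ParameterDef]
    perturbations: dict = field(default_factory=lambda: {"default": None})
    solution: Optional[Callable] = None

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValidationError(f"model {self.name}: duplicate parameter names")
        if len(self.initial_values) != len(self.state_names):
            raise ValidationError(
                f"model {self.name}: initial_values must match state_names"
            )
        for iv in self.initial_values:
            if isinstance(iv, str) and iv not in names:
                raise ValidationError(f"model {self.name}: unknown initial {iv!r}")
        if "default" not in self.perturbations:
            raise ValidationError(f"model {self.name}: no default perturbation")
        # smoke-check the rhs returns finite derivatives of the right length
        x0 = self.initial_state(self.defaults())
        dx = np.asarray(
            self.rhs(0.0, x0, self.to_linear(self.defaults()), self.perturbations["default"]),
            float,
        )
        if dx.shape != (len(self.state_names),) or not np.all(np.isfinite(dx)):
            raise ValidationError(f"model {self.name}: rhs is not well-formed")

    # --- parameter bookkeeping -------------------------------------------------
    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def parameter(self, name: str) -> ParameterDef:
        for p in self.parameters:
            if p.name == name:
                return p
        raise ValidationError(f"model {self.name}: unknown parameter {name!r}")

    def index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise ValidationError(f"model {self.name}: unknown parameter {name!r}") from None

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([p.lower_bound for p in self.parameters], float)
        hi = np.array([p.upper_bound for p in self.parameters], float)
        return lo, hi

    def defaults(self) -> np.ndarray:
        return np.array([p.default for p in self.parameters], float)

    def check_theta(self, theta) -> np.ndarray:
        theta = np.asarray(theta, float)
        if theta.shape != (len(self.parameters),):
            raise ValidationError(
                f"model {self.name}: theta has length {theta.size}, "
                f"expected {len(self.parameters)}"
            )
        lo, hi = self.bounds()
        eps = 1e-9 * np.maximum(1.0, hi - lo)
        if np.any(theta < lo - eps) or np.any(theta > hi + eps):
            bad = [
                self.parameters[i].name
                for i in range(theta.size)
                if not (lo[i] - eps[i] <= theta[i] <= hi[i] + eps[i])
            ]
            raise ValidationError(f"model {self.name}: theta out of bounds for {bad}")
        return theta

    def to_linear(self, theta) -> dict:
        """Map a parameter vector (stated scales) to a name -> linear-value dict."""
        theta = np.asarray(theta, float)
        return {
            p.name: p.to_linear(theta[i]) for i, p in enumerate(self.parameters)
        }

    def initial_state(self, theta) -> np.ndarray:
        p = self.to_linear(theta)
        return np.array(
            [p[iv] if isinstance(iv, str) else float(iv) for iv in self.initial_values],
            float,
        )

    def observable(self, name: str) -> ObservableDef:
        for obs in self.observables:
            if obs.name == name:
                return obs
        raise ValidationError(f"model {self.name}: unknown observable {name!r}")

    def resolve_perturbation(self, perturbation: str):
        # an id absent from the registry behaves as the default perturbation
        return self.perturbations.get(perturbation, self.perturbations["default"])


# --- simulation ----------------------------------------------------------------


def simulate_states(
    model: OdeModel,
    theta,
    perturbation: str = "default",
    times: Sequence[float] = (),
    config: Config = DEFAULT,
) -> np.ndarray:
    """Integrate the model and return states at ``times`` (n_times x n_states).

    Uses the model's closed-form solution when available and enabled in the
    config, otherwise a stiff-capable LSODA integration with the configured
    tolerances.
    """
    theta = model.check_theta(theta)
    times = np.asarray(times, float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValidationError("times must be sorted ascending and non-negative")
    p = model.to_linear(theta)
    u = model.resolve_perturbation(perturbation)

    if model.solution is not None and config.use_analytic:
        traj = np.asarray(model.solution(p, u, times), float)
        if not np.all(np.isfinite(traj)):
            raise IntegrationError(
                f"model {model.name}: non-finite closed-form trajectory", theta
            )
        return traj

    x0 = model.initial_state(theta)
    t_max = float(times[-1])
    if t_max == 0.0:
        return np.tile(x0, (times.size, 1))
    sol = solve_ivp(
        model.rhs,
        (0.0, t_max),
        x0,
        t_eval=times,
        args=(p, u),
        method="LSODA",
        rtol=config.rtol,
        atol=config.atol,
        dense_output=False,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"model {model.name}: integration failed ({sol.message})", theta
        )
    return sol.y.T


def _to_data_scale(obs: ObservableDef, value: float, condition=None) -> float:
    if obs.data_scale == "linear":
        return float(value)
    if value <= 0:
        label = condition.label() if condition is not None else obs.name
        raise NumericalError(
            f"non-positive prediction for log10-scale observable at {label}"
        )
    return math.log10(value)


def predict_observable(
    model: OdeModel,
    theta,
    condition: ExperimentalCondition,
    config: Config = DEFAULT,
) -> float:
    """Model prediction for one experimental condition, on the data scale."""
    obs = model.observable(condition.observable)
    x = simulate_states(model, theta, condition.perturbation, [condition.time], config)[0]
    xd = dict(zip(model.state_names, x))
    p = model.to_linear(theta)
    return _to_data_scale(obs, obs.mapping(xd, p), condition)


def predict_conditions(
    model: OdeModel,
    theta,
    conditions: Sequence[ExperimentalCondition],
    config: Config = DEFAULT,
) -> np.ndarray:
    """Predictions for many conditions, simulating once per perturbation."""
    theta = model.check_theta(theta)
    out = np.empty(len(conditions), float)
    by_pert: dict[str, list[int]] = {}
    for i, c in enumerate(conditions):
        by_pert.setdefault(c.perturbation, []).append(i)
    p = model.to_linear(theta)
    for pert, idxs in by_pert.items():
        ts = np.array([conditions[i].time for i in idxs], float)
        uniq, inverse = np.unique(ts, return_inverse=True)
        traj = simulate_states(model, theta, pert, uniq, config)
        for k, i in enumerate(idxs):
            c = conditions[i]
            obs = model.observable(c.observable)
            xd = dict(zip(model.state_names, traj[inverse[k]]))
            out[i] = _to_data_scale(obs, obs.mapping(xd, p), c)
    return out


def resolve_sigma(
    model: OdeModel,
    point: DataPoint,
    theta=None,
    x: Optional[dict] = None,
) -> float:
    """Measurement standard deviation for a point: known sigma or error model."""
    if point.sigma is not None:
        return float(point.sigma)
    obs = model.observable(point.condition.observable)
    if isinstance(obs.sigma, (int, float)):
        return float(obs.sigma)
    if isinstance(obs.sigma, str):
        if theta is None:
            raise ValidationError("parametric sigma requires a parameter vector")
        pdef = model.parameter(obs.sigma)
        return pdef.to_linear(np.asarray(theta, float)[model.index(obs.sigma)])
    if theta is None:
        raise ValidationError("state-dependent sigma requires a parameter vector")
    return float(obs.sigma(x or {}, model.to_linear(theta)))


def dataset_is_parametric_sigma(model: OdeModel, dataset: Dataset) -> bool:
    """True when any point's sigma depends on model parameters."""
    for pt in dataset:
        if pt.sigma is None:
            obs = model.observable(pt.condition.observable)
            if not isinstance(obs.sigma, (int, float)):
                return True
    return False


# --- dataset I/O ----------------------------------------------------------------

_CSV_COLUMNS = ("observable", "time", "perturbation", "value")


def read_dataset(path: str | Path, model: Optional[OdeModel] = None) -> Dataset:
    """Read a measurement table (observable,time,perturbation,value[,sigma]).

    When a model is given, observable names are validated against it; parse
    problems are reported with the 1-based file row number.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file without header") from None
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    has_sigma = "sigma" in df.columns
    known = None if model is None else {o.name for o in model.observables}
    points = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # header is row 1
        obs = str(row["observable"])
        if known is not None and obs not in known:
            raise ValidationError(f"{path}:{rowno}: unknown observable {obs!r}")
        try:
            t = float(row["time"])
            value = float(row["value"])
        except (TypeError, ValueError):
            raise ValidationError(f"{path}:{rowno}: non-numeric time or value") from None
        if t < 0:
            raise ValidationError(f"{path}:{rowno}: negative time {t}")
        if not np.isfinite(value):
            raise ValidationError(f"{path}:{rowno}: non-finite value")
        sigma = None
        if has_sigma and pd.notna(row["sigma"]):
            sigma = float(row["sigma"])
            if sigma <= 0:
                raise ValidationError(f"{path}:{rowno}: sigma must be positive")
        pert = row.get("perturbation", "default")
        pert = "default" if pd.isna(pert) else str(pert)
        points.append(
            DataPoint(ExperimentalCondition(obs, t, pert), value, sigma)
        )
    return Dataset(points)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_candidates(path: str | Path, model: Optional[OdeModel] = None) -> list[ExperimentalCondition]:
    """Read a candidate-design table (observable,time[,perturbation])."""
    df = pd.read_csv(path)
    for col in ("observable", "time"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    known = None if model is None else {o.name for o in model.observables}
    out = []
    for i, row in df.iterrows():
        obs = str(row["observable"])
        if known is not None and obs not in known:
            raise ValidationError(f"{path}:{int(i) + 2}: unknown observable {obs!r}")
        pert = row.get("perturbation", "default")
        pert = "default" if pd.isna(pert) else str(pert)
        out.append(ExperimentalCondition(obs, float(row["time"]), pert))
    return out
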