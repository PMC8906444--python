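"""Built-in example models, synthetic data generators and censoring.

Two ODE systems exercise every pipeline stage without external data:

* the ABC chain A -> B -> C (rates p1, p2, unknown initial amount A0),
  with state A unobserved by default and log-normal measurement noise of
  sigma_log = 0.2 on the observed states B and C; and
* a six-state erythropoietin (EPO) receptor-trafficking / degradation
  model: ligand binding, complex internalization, recycling and
  degradation, observed through three composite EPO pools (external,
  membrane, internal).

The ABC ground-truth rates and observation times are repository choices
(chosen so that, from two early observations each of B and C, the
conversion rate p2 is identifiable while p1 and A0 are not); only
log10(A0) = 0 and sigma_log = 0.2 are fixed by the study conditions.  The
EPO ground truth is a synthetic surrogate for desk-scale runs; it does not
reproduce any published parameter estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .model import (
    DataPoint,
    Dataset,
    ExperimentalCondition,
    NumericalError,
    ObservableDef,
    OdeModel,
    ParameterDef,
    predict_conditions,
)

ABC_SIGMA_LOG = 0.2
EPO_SIGMA_LOG = 0.1


@dataclass
class TrueModelSpec:
    """Ground truth for a synthetic study: model, true parameters, design."""

    model: OdeModel
    theta_true: np.ndarray          # on the parameters' stated scales
    noise_sd_log: float
    design_points: list[tuple[ExperimentalCondition, int]]  # (condition, replicates)
    default_seed: int = 1

    def __post_init__(self):
        self.model.check_theta(self.theta_true)
        if self.noise_sd_log <= 0:
            raise ValueError("noise_sd_log must be positive")


# --- ABC chain ------------------------------------------------------------------


def _abc_rhs(t, x, p, u):
    a, b, _ = x
    return [-p["p1"] * a, p["p1"] * a - p["p2"] * b, p["p2"] * b]


def _abc_solution(p, u, times):
    """Closed-form trajectories of the linear chain (handles p1 ~ p2)."""
    t = np.asarray(times, float)
    p1, p2, a0 = p["p1"], p["p2"], p["A0"]
    a = a0 * np.exp(-p1 * t)
    if abs(p1 - p2) <= 1e-9 * max(p1, p2, 1e-300):
        b = a0 * p1 * t * np.exp(-p1 * t)
    else:
        b = a0 * p1 / (p2 - p1) * (np.exp(-p1 * t) - np.exp(-p2 * t))
    c = np.maximum(a0 - a - b, 0.0)
    return np.column_stack([a, b, c])


def abc_model() -> OdeModel:
    """Linear chain A -> B -> C with free {p1, p2, A0} on the log10 axis.

    B and C start at zero (known); all three states are registered as
    log10-scale observables with constant sigma_log = 0.2, but A is simply
    never present in the default dataset - it exists so that measuring A
    can be proposed as a candidate design.
    """
    params = [
        ParameterDef("p1", "dynamic", "log10", -5.0, 3.0, -1.0),
        ParameterDef("p2", "dynamic", "log10", -5.0, 3.0, -1.0),
        ParameterDef("A0", "initial", "log10", -5.0, 3.0, 0.0),
    ]
    # assay dynamic range: concentrations measurable over ~12 decades
    rng = (-8.0, 4.0)
    obs = [
        ObservableDef("A", lambda x, p: x["A"], "log10", ABC_SIGMA_LOG, rng),
        ObservableDef("B", lambda x, p: x["B"], "log10", ABC_SIGMA_LOG, rng),
        ObservableDef("C", lambda x, p: x["C"], "log10", ABC_SIGMA_LOG, rng),
    ]
    return OdeModel(
        name="abc",
        state_names=["A", "B", "C"],
        rhs=_abc_rhs,
        initial_values=["A0", 0.0, 0.0],
        observables=obs,
        parameters=params,
        solution=_abc_solution,
    )


#: true ABC parameters on log10 scale: p1 = 0.05, p2 = 0.1, A0 = 1
ABC_THETA_TRUE = np.array([math.log10(0.05), math.log10(0.1), 0.0])
#: early observation times for B and C (well before the B peak at ~13.9)
ABC_DATA_TIMES = (3.0, 6.0)
#: the design time used for the candidate measurements of A, B and C
ABC_CANDIDATE_TIME = 40.0


def abc_reference_spec(seed: int = 1) -> TrueModelSpec:
    """Seeded ABC study: sparse early data for B and C, A unobserved."""
    model = abc_model()
    design = [
        (ExperimentalCondition(obs, t), 1)
        for obs in ("B", "C")
        for t in ABC_DATA_TIMES
    ]
    return TrueModelSpec(model, ABC_THETA_TRUE.copy(), ABC_SIGMA_LOG, design, seed)


def abc_candidates() -> list[ExperimentalCondition]:
    """The three candidate measurements: A, B or C at t = 40."""
    return [ExperimentalCondition(s, ABC_CANDIDATE_TIME) for s in ("A", "B", "C")]


# --- EPO degradation ------------------------------------------------------------


def _epo_rhs(t, x, p, u):
    epor, epo, cplx, cplx_i, depo_i, depo_e = x
    bind = p["k_on"] * epo * epor
    return [
        p["k_t"] * (p["EpoR0"] - epor) - bind + p["k_off"] * cplx + p["k_ex"] * cplx_i,
        -bind + p["k_off"] * cplx + p["k_ex"] * cplx_i,
        bind - p["k_off"] * cplx - p["k_e"] * cplx,
        p["k_e"] * cplx - p["k_de"] * cplx_i - p["k_di"] * cplx_i - p["k_ex"] * cplx_i,
        p["k_di"] * cplx_i,
        p["k_de"] * cplx_i,
    ]


def epo_model() -> OdeModel:
    """Six-state EPO receptor-trafficking model with three composite observables.

    States: free receptor (EpoR), extracellular EPO (Epo), membrane complex
    (EpoEpoR), internalized complex (EpoEpoR_i), internally degraded EPO
    (dEpo_i) and externally degraded EPO (dEpo_e).  Receptor turnover
    (k_t) replenishes EpoR toward EpoR0; binding/unbinding (k_on, k_off),
    internalization (k_e), recycling (k_ex) and degradation (k_de, k_di)
    move EPO between pools.  The total EPO over the five EPO-containing
    states is conserved.  Observables carry one free scale parameter each.
    """
    params = [
        ParameterDef("k_t", "dynamic", "log10", -3.0, 3.0, -1.5),
        ParameterDef("k_on", "dynamic", "log10", -3.0, 3.0, 0.7),
        ParameterDef("k_off", "dynamic", "log10", -3.0, 3.0, -1.3),
        ParameterDef("k_ex", "dynamic", "log10", -3.0, 3.0, -1.3),
        ParameterDef("k_e", "dynamic", "log10", -3.0, 3.0, -0.5),
        ParameterDef("k_de", "dynamic", "log10", -3.0, 3.0, -1.0),
        ParameterDef("k_di", "dynamic", "log10", -3.0, 3.0, -1.15),
        ParameterDef("Epo0", "initial", "log10", -2.0, 2.0, 0.0),
        ParameterDef("EpoR0", "initial", "log10", -2.0, 2.0, math.log10(0.5)),
        ParameterDef("s_ext", "observation", "log10", -2.0, 2.0, 0.0),
        ParameterDef("s_mem", "observation", "log10", -2.0, 2.0, 0.0),
        ParameterDef("s_int", "observation", "log10", -2.0, 2.0, 0.0),
    ]
    rng = (-6.0, 4.0)  # assay dynamic range on the log10 scale
    obs = [
        ObservableDef(
            "EPO_external",
            lambda x, p: p["s_ext"] * (x["Epo"] + x["dEpo_e"]),
            "log10",
            EPO_SIGMA_LOG,
            rng,
        ),
        ObservableDef(
            "EPO_membrane",
            lambda x, p: p["s_mem"] * x["EpoEpoR"],
            "log10",
            EPO_SIGMA_LOG,
            rng,
        ),
        ObservableDef(
            "EPO_internal",
            lambda x, p: p["s_int"] * (x["EpoEpoR_i"] + x["dEpo_i"]),
            "log10",
            EPO_SIGMA_LOG,
            rng,
        ),
    ]
    return OdeModel(
        name="epo",
        state_names=["EpoR", "Epo", "EpoEpoR", "EpoEpoR_i", "dEpo_i", "dEpo_e"],
        rhs=_epo_rhs,
        initial_values=["EpoR0", "Epo0", 0.0, 0.0, 0.0, 0.0],
        observables=obs,
        parameters=params,
    )


#: synthetic EPO surrogate truth (log10 scale; = the model defaults)
EPO_THETA_TRUE = epo_model().defaults()
#: 8-point time grid per observable; censoring half leaves 4 late points out
EPO_DATA_TIMES = (1.0, 2.0, 4.0, 6.0, 10.0, 15.0, 22.0, 30.0)


def epo_reference_spec(seed: int = 1) -> TrueModelSpec:
    """Seeded synthetic EPO study: 8 time points for each of 3 observables."""
    model = epo_model()
    design = [
        (ExperimentalCondition(obs.name, t), 1)
        for obs in model.observables
        for t in EPO_DATA_TIMES
    ]
    return TrueModelSpec(model, EPO_THETA_TRUE.copy(), EPO_SIGMA_LOG, design, seed)


# --- data generation and censoring ----------------------------------------------


def simulate_dataset(spec: TrueModelSpec, seed: Optional[int] = None) -> Dataset:
    """Simulate measurements: prediction at truth plus N(0, sigma_log) noise.

    Noise is additive on the (log10) data scale, i.e. log-normal on the
    linear scale.  Reproducible for a fixed seed; predictions are computed
    once per distinct condition.
    """
    seed = spec.default_seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    conds = [c for c, _ in spec.design_points]
    try:
        preds = predict_conditions(spec.model, spec.theta_true, conds)
    except NumericalError as exc:
        raise NumericalError(f"true-model prediction failed: {exc}") from exc
    points = []
    for (cond, reps), mu in zip(spec.design_points, preds):
        for _ in range(int(reps)):
            points.append(
                DataPoint(cond, float(mu + rng.normal(0.0, spec.noise_sd_log)), None)
            )
    return Dataset(points)


def censor_dataset(dataset: Dataset, fraction: float = 0.5) -> tuple[Dataset, Dataset]:
    """Split off the late-time half of the data, per observable.

    For each observable the latest ceil(fraction * n_distinct_times) time
    points (with all their replicates) go to the held-out set; the rest is
    kept.  Returns (kept, held_out); together they partition the dataset.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    late: dict[str, set] = {}
    times: dict[str, list] = {}
    for pt in dataset:
        times.setdefault(pt.condition.observable, [])
        if pt.condition.time not in times[pt.condition.observable]:
            times[pt.condition.observable].append(pt.condition.time)
    for obs, ts in times.items():
        ts_sorted = sorted(ts)
        k = math.ceil(fraction * len(ts_sorted))
        late[obs] = set(ts_sorted[len(ts_sorted) - k :])
    kept, held = [], []
    for pt in dataset:
        if pt.condition.time in late[pt.condition.observable]:
            held.append(pt)
        else:
            kept.append(pt)
    return Dataset(kept), Dataset(held)


# --- measurement oracles for the sequential loop --------------------------------


def simulation_oracle(spec: TrueModelSpec, seed: int = 0) -> Callable:
    """Oracle drawing noisy measurements from the ground truth."""
    rng = np.random.default_rng(seed)

    def oracle(condition: ExperimentalCondition) -> float:
        mu = predict_conditions(spec.model, spec.theta_true, [condition])[0]
        return float(mu + rng.normal(0.0, spec.noise_sd_log))

    return oracle


def replay_oracle(held_out: Dataset) -> Callable:
    """Oracle replaying held-out data (replicates averaged)."""
    table: dict[ExperimentalCondition, list[float]] = {}
    for pt in held_out:
        table.setdefault(pt.condition, []).append(pt.value)

    def oracle(condition: ExperimentalCondition) -> float:
        if condition not in table:
            raise NumericalError(f"no held-out measurement for {condition.label()}")
        return float(np.mean(table[condition]))

    return oracle


# --- linear-Gaussian reference model --------------------------------------------


def line_model(sigma: float = 0.1) -> OdeModel:
    """Straight line y = a t + b as a degenerate ODE (dy/dt = a, y(0) = b).

    Gaussian errors with known constant sigma on the linear scale.  The
    closed-form least-squares solution makes this the analytic reference
    for the fitting, profiling and design machinery.
    """
    params = [
        ParameterDef("a", "dynamic", "linear", -10.0, 10.0, 1.0),
        ParameterDef("b", "initial", "linear", -10.0, 10.0, 0.0),
    ]
    return OdeModel(
        name="line",
        state_names=["y"],
        rhs=lambda t, x, p, u: [p["a"]],
        initial_values=["b"],
        observables=[ObservableDef("y", lambda x, p: x["y"], "linear", sigma)],
        parameters=params,
        solution=lambda p, u, times: (p["b"] + p["a"] * np.asarray(times, float))[:, None],
    )


def line_reference_spec(
    a: float = 1.0,
    b: float = 0.5,
    xs: tuple = (0.0, 1.0, 2.0, 3.0),
    sigma: float = 0.1,
    seed: int = 1,
) -> TrueModelSpec:
    model = line_model(sigma)
    design = [(ExperimentalCondition("y", float(t)), 1) for t in xs]
    return TrueModelSpec(model, np.array([a, b]), sigma, design, seed)
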