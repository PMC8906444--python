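"""Run configuration shared across fitting, profiling and design.

Every numerical knob lives here with a default, so that a run can be
reproduced from the serialized config alone.  Fields are grouped by the
stage they control; all are plain floats/ints so the config round-trips
through YAML/JSON without loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    # --- ODE integration ---
    rtol: float = 1e-8
    atol: float = 1e-10
    use_analytic: bool = True  # use a model's closed-form solution when it has one

    # --- optimization ---
    n_starts: int = 20       # multistart budget for initial fits
    gtol: float = 1e-8
    xtol: float = 1e-10
    ftol: float = 1e-10
    seed: int = 0

    # --- profile stepping ---
    level: float = 0.95            # CI level defining profile extent
    margin: float = 0.5            # extra -2 log LR beyond threshold before stopping
    target_dpl_frac: float = 0.1   # step controller target, fraction of the threshold
    max_steps_per_side: int = 100
    initial_step_frac: float = 0.01  # of the bound span (or outcome scale for VPL)
    min_step_frac: float = 1e-6
    max_step_frac: float = 0.25
    drop_tolerance: float = 0.2    # max fraction of failed grid points / rows

    # --- uncertainty summary ---
    alpha_max: float = 0.95  # cap on the confidence level in the average width
    n_alpha: int = 50        # quadrature nodes on [0, alpha_max]

    # --- two-dimensional profiles / design ---
    n_z_rows: int = 19       # measurement-outcome rows per 2D profile
    pred_cap: float = 0.95   # two-sided predictive confidence cap for row placement
    reg_lambda: float = 0.1  # weak quadratic prior weight for unbounded predictions

    def replace(self, **kw) -> "Config":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


DEFAULT = Config()
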