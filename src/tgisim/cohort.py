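"""Synthetic mouse cohorts mirroring the original tumor-growth study design.

The emulated experiment: 40 female mice bearing mammary tumors — 21 untreated
controls and 19 treated with a single 5 mg/kg cisplatin bolus on day 0 — with
tumor volumes recorded daily except weekends (and holidays) over ~50 days.
Between-animal variability is lognormal on a chosen parameter subset
(``theta_i = theta_pop * exp(eta_i)``, ``eta_i ~ N(0, omega^2)``), and
measurements carry combined additive + proportional noise

    y = w * (1 + eps_prop) + eps_add,   truncated at 0,

the standard pharmacometric residual model.  Volumes are in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pk import DoseSchedule, PKParams
from .regimens import CONTROL
from .tumor import DEMO_TRANSIT, DelayParams, TumorParams, simulate_dde, simulate_transit

__all__ = [
    "PopulationParams",
    "SamplingDesign",
    "Cohort",
    "design_days",
    "generate_cohort",
    "DEFAULT_TREATED_SCHEDULE",
]

#: The treated arm's regimen in the emulated study: 5 mg/kg on day 0.
DEFAULT_TREATED_SCHEDULE = DoseSchedule([(0.0, 5.0)], name="bolus")

#: Parameters given between-animal lognormal variability by default; the
#: remaining parameters are fixed at their population value, which keeps the
#: recovery problem well-posed at n = 40.
DEFAULT_VARIABLE_PARAMS = ("lambda0", "k2", "w0")


@dataclass(frozen=True)
class PopulationParams:
    """Population-typical model parameters plus variability and noise.

    ``omega`` maps parameter names to lognormal between-animal standard
    deviations (of the log); parameters absent from ``omega`` are identical
    across animals.  ``sigma_add`` (volume units) and ``sigma_prop``
    (fraction) define the combined residual error.
    """

    theta: TumorParams | DelayParams = DEMO_TRANSIT
    omega: Mapping[str, float] = field(
        default_factory=lambda: {p: 0.2 for p in DEFAULT_VARIABLE_PARAMS}
    )
    sigma_add: float = 5.0
    sigma_prop: float = 0.1
    seed: int = 0

    def __post_init__(self):
        valid = set(self.theta.to_dict())
        for name, sd in self.omega.items():
            if name not in valid:
                raise ValueError(f"omega refers to unknown parameter {name!r}")
            if sd < 0:
                raise ValueError(f"omega[{name!r}] must be >= 0")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual error sds must be >= 0")


@dataclass(frozen=True)
class SamplingDesign:
    """Measurement days: daily within ``[start_day, end_day]`` except excluded
    weekdays (default Saturday/Sunday with day 0 anchored to Monday) and
    holidays."""

    start_day: int = 0
    end_day: int = 50
    excluded_weekdays: frozenset[int] = frozenset({5, 6})
    holidays: frozenset[int] = frozenset()
    day0_weekday: int = 0  # 0 = Monday

    def __init__(
        self,
        start_day: int = 0,
        end_day: int = 50,
        excluded_weekdays=frozenset({5, 6}),
        holidays=frozenset(),
        day0_weekday: int = 0,
    ):
        if start_day > end_day:
            raise ValueError("start_day must be <= end_day")
        if not 0 <= day0_weekday <= 6:
            raise ValueError("day0_weekday must be in 0..6")
        object.__setattr__(self, "start_day", int(start_day))
        object.__setattr__(self, "end_day", int(end_day))
        object.__setattr__(self, "excluded_weekdays", frozenset(int(d) for d in excluded_weekdays))
        object.__setattr__(self, "holidays", frozenset(int(d) for d in holidays))
        object.__setattr__(self, "day0_weekday", int(day0_weekday))


def design_days(design: SamplingDesign) -> list[int]:
    """All measurement days implied by a sampling design (never empty)."""
    days = [
        d
        for d in range(design.start_day, design.end_day + 1)
        if (d + design.day0_weekday) % 7 not in design.excluded_weekdays
        and d not in design.holidays
    ]
    if not days:
        raise ValueError("sampling design produces no measurement days")
    return days


@dataclass(frozen=True)
class Cohort:
    """A simulated study cohort.

    ``measurements`` columns: ``animal_id, arm, day, volume``.
    ``true_params`` columns: ``animal_id, param, value`` (the simulated
    truth; withhold it to run fits blind).
    """

    measurements: pd.DataFrame
    true_params: pd.DataFrame
    model: str
    pk: PKParams
    treated_schedule: DoseSchedule
    population: PopulationParams
    design: SamplingDesign

    @property
    def n_animals(self) -> int:
        return self.measurements["animal_id"].nunique()

    @property
    def arms(self) -> pd.Series:
        return self.measurements.groupby("animal_id")["arm"].first()

    def animal_params(self, animal_id: str) -> dict[str, float]:
        sub = self.true_params[self.true_params["animal_id"] == animal_id]
        return dict(zip(sub["param"], sub["value"]))

    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write measurements; the truth sidecar only when a path is given."""
        self.measurements.to_csv(path, index=False, float_format="%.12g")
        if truth_path is not None:
            self.true_params.to_csv(truth_path, index=False, float_format="%.12g")


def _draw_individual(
    theta: TumorParams | DelayParams,
    omega: Mapping[str, float],
    rng: np.random.Generator,
) -> TumorParams | DelayParams:
    updates = {}
    # sorted for draw-order stability across dict orderings
    for name in sorted(omega):
        sd = omega[name]
        eta = rng.normal(0.0, sd) if sd > 0 else 0.0
        updates[name] = getattr(theta, name) * math.exp(eta)
    return replace(theta, **updates)


def generate_cohort(
    pop: PopulationParams,
    design: SamplingDesign | None = None,
    n_control: int = 21,
    n_treated: int = 19,
    model: str = "transit",
    *,
    pk: PKParams | None = None,
    treated_schedule: DoseSchedule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Cohort:
    """Simulate a cohort: parameter draws, true trajectories, noisy readings.

    Controls receive the empty schedule, treated animals the 5 mg/kg day-0
    bolus by default.  Fully reproducible from ``pop.seed``.
    """
    if model not in ("transit", "dde"):
        raise ValueError(f"unknown model tag {model!r} (expected 'transit' or 'dde')")
    if model == "transit" and not isinstance(pop.theta, TumorParams):
        raise ValueError("model 'transit' requires TumorParams population values")
    if model == "dde" and not isinstance(pop.theta, DelayParams):
        raise ValueError("model 'dde' requires DelayParams population values")
    if n_control < 0 or n_treated < 0:
        raise ValueError("cohort sizes must be >= 0")
    design = design if design is not None else SamplingDesign()
    pk = pk if pk is not None else PKParams()
    treated_schedule = (
        treated_schedule if treated_schedule is not None else DEFAULT_TREATED_SCHEDULE
    )

    days = np.array(design_days(design), dtype=float)
    t_grid = np.unique(np.concatenate([[0.0], days]))
    rng = np.random.default_rng(pop.seed)
    simulate = simulate_transit if model == "transit" else simulate_dde

    meas_rows = []
    truth_rows = []
    arms = [("control", i, CONTROL) for i in range(n_control)] + [
        ("treated", i, treated_schedule) for i in range(n_treated)
    ]
    for arm, idx, schedule in arms:
        animal_id = f"{arm[0].upper()}{idx + 1:02d}"
        theta_i = _draw_individual(pop.theta, pop.omega, rng)
        traj = simulate(theta_i, schedule, pk, t_grid, rtol=rtol, atol=atol)
        w_true = np.interp(days, traj.t, traj.w)
        eps_prop = rng.normal(0.0, pop.sigma_prop, size=len(days)) if pop.sigma_prop > 0 else 0.0
        eps_add = rng.normal(0.0, pop.sigma_add, size=len(days)) if pop.sigma_add > 0 else 0.0
        y = np.maximum(w_true * (1.0 + eps_prop) + eps_add, 0.0)
        for d, v in zip(days, y):
            meas_rows.append({"animal_id": animal_id, "arm": arm, "day": d, "volume": v})
        for name, value in theta_i.to_dict().items():
            truth_rows.append({"animal_id": animal_id, "param": name, "value": value})

    return Cohort(
        measurements=pd.DataFrame(meas_rows),
        true_params=pd.DataFrame(truth_rows),
        model=model,
        pk=pk,
        treated_schedule=treated_schedule,
        population=pop,
        design=design,
    )
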