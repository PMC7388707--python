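"""One-compartment bolus pharmacokinetics with first-order elimination.

Cisplatin is modelled as an instantaneous intravenous bolus eliminated with
first-order kinetics (half-life ``t_half``, rate ``k_e = ln 2 / t_half``).
Because the kinetics are linear, multi-dose concentration profiles obey the
superposition principle: the concentration at time ``t`` is the sum of the
remaining concentrations of every dose administered up to ``t``,

    c(t) = s * sum_{i : t_i <= t} D_i * exp(-k_e * (t - t_i)),

where ``s`` is a concentration scale (units of concentration per mg/kg;
default 1, i.e. concentration is numerically the remaining dose in mg/kg —
the volume of distribution is folded into the drug-potency parameter of the
tumor model). AUCs over arbitrary intervals, including ``[t0, inf)``, follow
in closed form.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DoseSchedule",
    "PKParams",
    "AUCResult",
    "half_life_to_rate",
    "rate_to_half_life",
    "concentration",
    "auc",
    "relative_auc_table",
    "auc_table_to_frame",
    "read_schedule_csv",
    "write_schedule_csv",
]

SCHEDULE_CSV_HEADER = ("time_days", "amount_mg_per_kg")


def half_life_to_rate(t_half: float) -> float:
    """First-order elimination rate constant (1/day) from a half-life (day)."""
    if not (math.isfinite(t_half) and t_half > 0):
        raise ValueError(f"half-life must be finite and > 0, got {t_half!r}")
    return math.log(2.0) / t_half


def rate_to_half_life(k_e: float) -> float:
    """Half-life (day) from a first-order rate constant (1/day); inverse of
    :func:`half_life_to_rate`."""
    if not (math.isfinite(k_e) and k_e > 0):
        raise ValueError(f"rate constant must be finite and > 0, got {k_e!r}")
    return math.log(2.0) / k_e


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered sequence of bolus events ``(time_days, amount_mg_per_kg)``.

    Event times must be strictly increasing and non-negative; every amount
    must be strictly positive.  An empty schedule (no events) is a valid
    untreated control.
    """

    events: tuple[tuple[float, float], ...]
    name: str = ""

    def __init__(self, events: Iterable[Sequence[float]], name: str = ""):
        ev = tuple((float(t), float(a)) for t, a in events)
        for t, a in ev:
            if not (math.isfinite(t) and t >= 0):
                raise ValueError(f"dose time must be finite and >= 0, got {t}")
            if not (math.isfinite(a) and a > 0):
                raise ValueError(f"dose amount must be finite and > 0, got {a}")
        times = [t for t, _ in ev]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "name", str(name))

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    @property
    def amounts(self) -> np.ndarray:
        return np.array([a for _, a in self.events], dtype=float)

    @property
    def total_dose(self) -> float:
        """Total administered dose in mg/kg (0 for the empty control)."""
        return float(sum(a for _, a in self.events))

    def __len__(self) -> int:
        return len(self.events)

    def shifted(self, dt: float) -> "DoseSchedule":
        """The same doses delayed by ``dt`` days."""
        return DoseSchedule([(t + dt, a) for t, a in self.events], name=self.name)

    def merged(self, other: "DoseSchedule", name: str = "") -> "DoseSchedule":
        """Union of two schedules; coincident times merge into one event."""
        pool: dict[float, float] = {}
        for t, a in (*self.events, *other.events):
            pool[t] = pool.get(t, 0.0) + a
        return DoseSchedule(sorted(pool.items()), name=name)


@dataclass(frozen=True)
class PKParams:
    """Pharmacokinetic settings: elimination half-life and concentration scale.

    Parameters
    ----------
    half_life_days
        Elimination half-life in days.  The default 6.9 d is the estimate for
        cisplatin in the treated cohort that this package models.
    concentration_scale
        Concentration units per mg/kg of administered dose.  With the default
        1.0, a D mg/kg bolus raises the concentration by D units, so the
        tumor-kill potency parameter absorbs the (unidentifiable) volume of
        distribution.
    """

    half_life_days: float = 6.9
    concentration_scale: float = 1.0

    def __post_init__(self):
        half_life_to_rate(self.half_life_days)  # validates
        if not (math.isfinite(self.concentration_scale) and self.concentration_scale > 0):
            raise ValueError("concentration_scale must be finite and > 0")

    @property
    def k_e(self) -> float:
        """Elimination rate constant ln(2)/t_half, per day."""
        return half_life_to_rate(self.half_life_days)


def concentration(schedule: DoseSchedule, pk: PKParams, t) -> np.ndarray | float:
    """Drug concentration at time(s) ``t`` by superposition of bolus decays.

    Accepts a scalar or array ``t``; times before the first dose give 0.
    The profile jumps upward by ``scale * D_i`` at each dose time ``t_i``
    (the dose is included for ``t >= t_i``) and decays exponentially in
    between.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("time(s) must be finite")
    c = np.zeros_like(t_arr)
    k = pk.k_e
    for ti, di in schedule.events:
        mask = t_arr >= ti
        c = c + np.where(mask, di * np.exp(-k * np.where(mask, t_arr - ti, 0.0)), 0.0)
    c = pk.concentration_scale * c
    return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c


def auc(schedule: DoseSchedule, pk: PKParams, t0: float, t1: float) -> float:
    """Area under the concentration curve on ``[t0, t1]`` in closed form.

    ``t1`` may be ``inf``; the exact value is

        sum_{i : t_i < t1} (s*D_i/k_e) * (exp(-k_e*max(0, t0-t_i)) - exp(-k_e*(t1-t_i))).
    """
    if not (math.isfinite(t0) and t0 < t1):
        raise ValueError(f"need finite t0 < t1, got [{t0}, {t1}]")
    k = pk.k_e
    total = 0.0
    for ti, di in schedule.events:
        if ti >= t1:
            continue
        upper = 0.0 if math.isinf(t1) else math.exp(-k * (t1 - ti))
        lower = math.exp(-k * max(0.0, t0 - ti))
        total += di / k * (lower - upper)
    return pk.concentration_scale * total


@dataclass(frozen=True)
class AUCResult:
    """One row of a relative-AUC table."""

    schedule: str
    t0_days: float
    t1_days: float
    auc_raw: float
    auc_relative: float


def relative_auc_table(
    schedules: Sequence[DoseSchedule],
    pk: PKParams,
    t0: float,
    t1: float,
    reference: DoseSchedule,
    anchor_value: float = 1.0,
) -> list[AUCResult]:
    """Relative AUCs on ``[t0, t1]``, normalized so ``reference`` maps to
    ``anchor_value``.

    The absolute concentration scale is unidentifiable without a volume of
    distribution, so AUC tables are reported relative to a reference
    schedule anchored at a chosen value (e.g. the day-0 bolus at its
    published 2.433).
    """
    ref_auc = auc(reference, pk, t0, t1)
    if ref_auc <= 0.0:
        raise ValueError("reference schedule has zero AUC on the interval")
    out = []
    for s in schedules:
        raw = auc(s, pk, t0, t1)
        out.append(
            AUCResult(
                schedule=s.name,
                t0_days=t0,
                t1_days=t1,
                auc_raw=raw,
                auc_relative=raw * anchor_value / ref_auc,
            )
        )
    return out


def auc_table_to_frame(results: Sequence[AUCResult]):
    """AUC results as a DataFrame with a 3-decimal presentation column."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "schedule": [r.schedule for r in results],
            "auc_raw": [r.auc_raw for r in results],
            "auc_relative": [r.auc_relative for r in results],
        }
    )
    df["auc_relative_3dp"] = df["auc_relative"].round(3)
    return df


def write_schedule_csv(schedule: DoseSchedule, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCHEDULE_CSV_HEADER)
        for t, a in schedule.events:
            w.writerow([repr(t), repr(a)])


def read_schedule_csv(path: str | Path, name: str | None = None) -> DoseSchedule:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or tuple(rows[0]) != SCHEDULE_CSV_HEADER:
        raise ValueError(f"{path}: expected header {','.join(SCHEDULE_CSV_HEADER)}")
    events = [(float(t), float(a)) for t, a in rows[1:]]
    return DoseSchedule(events, name=name if name is not None else path.stem)
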