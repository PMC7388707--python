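"""Tumor-growth-inhibition dynamics: transit-compartment and delay variants.

Unperturbed growth follows the Simeoni form — exponential at small burden,
linear at large burden, with a smooth switch of sharpness ``psi``:

    dw/dt = lambda0 * w * [1 + ((lambda0/lambda1) * w)**psi]**(-1/psi).

Drug action is a first-order kill on proliferating cells, proportional to
the concentration ``c(t)``.  Two mechanisms of delayed cell death are
implemented behind a common integration contract:

* **Transit chain** — cells hit by the drug traverse ``n_transit``
  first-order damage compartments (rate ``k1``) before elimination, giving
  an Erlang-distributed lag with mean ``n_transit / k1``:

      dx1/dt = lambda0*x1*g(w) - k2*c(t)*x1
      dx2/dt = k2*c(t)*x1 - k1*x2
      dxj/dt = k1*(x_{j-1} - x_j),   j = 3..n_transit+1

  with ``w = sum_j x_j`` and ``g`` the growth-saturation factor above.

* **Fixed delay (DDE)** — a cell hit at time ``s`` is removed at ``s + tau``;
  the damaged pool ``x2`` gains ``k2*c(t)*x1(t)`` and loses
  ``k2*c(t-tau)*x1(t-tau)``, integrated by the method of steps.

In both variants the growth denominator uses the total burden ``w`` (all
compartments).  A tumor in the exponential regime shrinks under a constant
concentration exceeding the eradication threshold ``lambda0 / k2``.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .pk import DoseSchedule, PKParams

__all__ = [
    "TumorParams",
    "DelayParams",
    "Trajectory",
    "SolverError",
    "unperturbed_growth_rate",
    "simulate_transit",
    "simulate_dde",
    "eradication_threshold",
    "DEMO_TRANSIT",
    "DEMO_DELAY",
]


class SolverError(RuntimeError):
    """Raised when the ODE/DDE integrator fails to meet its tolerances.

    Carries ``last_t``, the last successfully accepted time.
    """

    def __init__(self, message: str, last_t: float | None = None):
        super().__init__(message)
        self.last_t = last_t


def _check_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class TumorParams:
    """Parameters of the transit-compartment tumor-growth-inhibition model.

    Attributes
    ----------
    lambda0 : float
        Exponential-phase growth rate, 1/day.
    lambda1 : float
        Linear-phase growth rate, volume/day.
    psi : float
        Sharpness of the exponential-to-linear switch (dimensionless, >= 1).
    k1 : float
        Transit rate through the damage compartments, 1/day.
    k2 : float
        Drug potency, 1/(concentration * day).
    w0 : float
        Initial tumor burden, volume units.
    n_transit : int
        Number of damage compartments (>= 1).
    """

    lambda0: float
    lambda1: float
    k1: float
    k2: float
    w0: float
    psi: float = 20.0
    n_transit: int = 3

    def __post_init__(self):
        for nm in ("lambda0", "lambda1", "k1", "k2", "w0"):
            _check_positive(nm, getattr(self, nm))
        if self.psi < 1:
            raise ValueError("psi must be >= 1")
        if int(self.n_transit) != self.n_transit or self.n_transit < 1:
            raise ValueError("n_transit must be an integer >= 1")

    def to_dict(self) -> dict:
        return {
            "lambda0": self.lambda0,
            "lambda1": self.lambda1,
            "k1": self.k1,
            "k2": self.k2,
            "w0": self.w0,
            "psi": self.psi,
            "n_transit": self.n_transit,
        }


@dataclass(frozen=True)
class DelayParams:
    """Parameters of the fixed-delay variant: as :class:`TumorParams` but the
    transit chain (``k1``, ``n_transit``) is replaced by a single death delay
    ``tau`` (days): a cell hit at time ``s`` is removed at ``s + tau``."""

    lambda0: float
    lambda1: float
    k2: float
    w0: float
    tau: float
    psi: float = 20.0

    def __post_init__(self):
        for nm in ("lambda0", "lambda1", "k2", "w0"):
            _check_positive(nm, getattr(self, nm))
        if self.psi < 1:
            raise ValueError("psi must be >= 1")
        if not (math.isfinite(self.tau) and self.tau >= 0):
            raise ValueError("tau must be finite and >= 0")

    def to_dict(self) -> dict:
        return {
            "lambda0": self.lambda0,
            "lambda1": self.lambda1,
            "k2": self.k2,
            "w0": self.w0,
            "tau": self.tau,
            "psi": self.psi,
        }


#: Demonstration parameter set used throughout the docs and qualitative
#: tests: a tumor of 50 volume units growing at 0.3/day (linear cap
#: 120 units/day), moderate drug potency 0.15 per conc-day so a 5 mg/kg
#: bolus transiently regresses the tumor but growth resumes well before
#: day 50, and a mean kill delay of 6 days (3 compartments at 0.5/day).
DEMO_TRANSIT = TumorParams(lambda0=0.3, lambda1=120.0, k1=0.5, k2=0.15, w0=50.0)

#: Fixed-delay counterpart of :data:`DEMO_TRANSIT` with tau = n_transit/k1.
DEMO_DELAY = DelayParams(lambda0=0.3, lambda1=120.0, k2=0.15, w0=50.0, tau=6.0)


def _scalar_concentration(schedule: DoseSchedule, pk: PKParams) -> Callable[[float], float]:
    """Fast scalar superposition concentration for ODE right-hand sides
    (equivalent to :func:`tgisim.pk.concentration`, without array plumbing)."""
    events = schedule.events
    k = pk.k_e
    scale = pk.concentration_scale
    if len(events) == 1:
        t0, d0 = events[0]

        def c1(tt: float) -> float:
            return scale * d0 * math.exp(-k * (tt - t0)) if tt >= t0 else 0.0

        return c1

    def c(tt: float) -> float:
        total = 0.0
        for ti, di in events:
            if ti > tt:
                break
            total += di * math.exp(-k * (tt - ti))
        return scale * total

    return c


#: Trial-state bound: healthy trajectories stay many orders of magnitude
#: below this, but a diverging solve can feed the RHS states that overflow
#: to inf/NaN, which is known to make LSODA spin indefinitely instead of
#: failing.  Raising aborts the solve immediately.
_STATE_BOUND = 1e100


def _guard_state(w: float, x1: float) -> None:
    if not (math.isfinite(w) and math.isfinite(x1) and abs(w) < _STATE_BOUND and abs(x1) < _STATE_BOUND):
        raise SolverError(f"state blow-up during integration (w={w!r})")


def _growth_factor(w: float, lambda0: float, lambda1: float, psi: float) -> float:
    # [1 + ((lambda0/lambda1) w)^psi]^(-1/psi), evaluated in log space so the
    # power term cannot overflow for large burdens.
    if w <= 0.0:
        return 1.0
    z = psi * math.log(w * lambda0 / lambda1)
    lse = z if z > 35.0 else math.log1p(math.exp(z))  # log(1 + e^z), overflow-safe
    return math.exp(-lse / psi)


def unperturbed_growth_rate(w: float, p: TumorParams | DelayParams) -> float:
    """Drug-free growth rate dw/dt (volume/day) at burden ``w``.

    Tends to ``lambda0 * w`` as ``w -> 0`` and saturates at ``lambda1`` as
    ``w -> inf``; at the switch burden ``lambda1/lambda0`` it equals
    ``lambda1 * 2**(-1/psi)``.
    """
    if not math.isfinite(w) or w < 0:
        raise ValueError(f"burden w must be finite and >= 0, got {w!r}")
    return p.lambda0 * w * _growth_factor(w, p.lambda0, p.lambda1, p.psi)


def eradication_threshold(p: TumorParams | DelayParams) -> float:
    """Constant concentration ``lambda0 / k2`` above which an
    exponential-regime tumor shrinks (net proliferation turns negative)."""
    return p.lambda0 / p.k2


@dataclass(frozen=True)
class Trajectory:
    """A simulated tumor time-course.

    ``states`` has one row per time point; columns are the proliferating
    compartment ``x1`` followed by the damaged compartments.  ``w`` is the
    total burden (row sum).
    """

    t: np.ndarray
    states: np.ndarray
    model: str
    params: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def w(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def n_states(self) -> int:
        return self.states.shape[1]

    def w_at(self, time: float) -> float:
        """Total burden at ``time`` (linear interpolation on the grid)."""
        return float(np.interp(time, self.t, self.w))

    def to_frame(self):
        import pandas as pd

        cols = {f"x{j + 1}": self.states[:, j] for j in range(self.n_states)}
        return pd.DataFrame({"time_days": self.t, **cols, "w": self.w})

    def to_csv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        """Write the trajectory as CSV; optional sidecar key-value metadata."""
        self.to_frame().to_csv(path, index=False, float_format="%.12g")
        if metadata_path is not None:
            lines = [f"model\t{self.model}"]
            lines += [f"{k}\t{v!r}" for k, v in sorted(self.params.items())]
            Path(metadata_path).write_text("\n".join(lines) + "\n")


def _prepare_grid(t_grid) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("t_grid must be a 1-D array with >= 2 points")
    if t[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return t


def _finalize_states(states: np.ndarray, atol: float) -> np.ndarray:
    # Harmless solver-noise negativity is clamped; anything beyond the
    # solver's own tolerance scale is a genuine failure.
    if not np.all(np.isfinite(states)):
        raise SolverError("integration produced non-finite states")
    neg_tol = max(1e-12, 10.0 * atol)
    worst = states.min(initial=0.0)
    if worst < -neg_tol:
        raise SolverError(f"negative compartment {worst:.3e} exceeds clip tolerance {neg_tol:.1e}")
    return np.clip(states, 0.0, None)


def _segment_edges(t_end: float, breakpoints: Sequence[float]) -> list[float]:
    pts = {0.0, t_end}
    for b in breakpoints:
        if 0.0 < b < t_end:
            pts.add(float(b))
    return sorted(pts)


#: Per-solve budget of RHS evaluations.  Healthy trajectories use a few
#: thousand; a solver grinding in a pathological parameter region (possible
#: during wild optimisation trial steps) is cut off and reported as a
#: SolverError instead of stalling for minutes.
_MAX_RHS_EVALS = 100_000


def _budgeted(rhs: Callable, budget: int = _MAX_RHS_EVALS) -> Callable:
    count = [0]

    def wrapped(t, x):
        count[0] += 1
        if count[0] > budget:
            raise SolverError(f"RHS evaluation budget ({budget}) exhausted", last_t=float(t))
        return rhs(t, x)

    return wrapped


def _integrate_segments(
    rhs: Callable,
    y0: np.ndarray,
    t_grid: np.ndarray,
    edges: list[float],
    rtol: float,
    atol: float,
    collect_dense: bool = False,
):
    """Piecewise integration restarted at each edge (concentration jumps make
    the RHS discontinuous there).  Returns states on ``t_grid`` and, if asked,
    the list of dense segment solutions for lagged evaluation."""
    rhs = _budgeted(rhs)
    n_times = len(t_grid)
    out = np.empty((n_times, len(y0)))
    out[0] = y0
    dense: list[tuple[float, float, object]] = []
    y = np.asarray(y0, dtype=float)
    nfev = 0
    for a, b in zip(edges, edges[1:]):
        inside = t_grid[(t_grid > a) & (t_grid <= b)]
        t_eval = np.unique(np.append(inside, b))
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            dense_output=collect_dense,
            rtol=rtol,
            atol=atol,
        )
        nfev += sol.nfev
        if not sol.success:
            raise SolverError(
                f"integration failed on [{a}, {b}]: {sol.message}",
                last_t=float(sol.t[-1]) if len(sol.t) else a,
            )
        if collect_dense:
            dense.append((a, b, sol.sol))
        for tt, yy in zip(sol.t, sol.y.T):
            idx = np.searchsorted(t_grid, tt)
            if idx < n_times and t_grid[idx] == tt:
                out[idx] = yy
        y = sol.y[:, -1]
    return out, dense, nfev


def simulate_transit(
    p: TumorParams,
    schedule: DoseSchedule,
    pk: PKParams,
    t_grid,
    *,
    conc_fn: Callable[[float], float] | None = None,
    extra_breakpoints: Sequence[float] = (),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    track_kill: bool = False,
) -> Trajectory:
    """Integrate the transit-compartment model over ``t_grid``.

    ``conc_fn`` overrides the superposition concentration (e.g. a constant
    exposure for threshold experiments); pass ``extra_breakpoints`` if the
    override itself is discontinuous.  With ``track_kill`` an auxiliary
    cumulative-death state ``integral of k1*x_last`` is appended, which
    together with the compartments conserves the mass killed.
    """
    t = _prepare_grid(t_grid)
    n = p.n_transit
    lam0, lam1, psi, k1, k2 = p.lambda0, p.lambda1, p.psi, p.k1, p.k2

    if conc_fn is None:
        conc_fn = _scalar_concentration(schedule, pk)
        breaks: list[float] = list(schedule.times)
    else:
        breaks = list(extra_breakpoints)

    n_states = n + 1 + (1 if track_kill else 0)

    def rhs(tt, x):
        w = x[: n + 1].sum()
        _guard_state(w, x[0])
        c = conc_fn(tt)
        hit = k2 * c * x[0]
        d = np.empty(n_states)
        # multiply x1 by the bounded product (factor * x1 <= lambda1/lambda0
        # for large w) so absurd trial states cannot overflow to inf
        d[0] = lam0 * (x[0] * _growth_factor(w, lam0, lam1, psi)) - hit
        d[1] = hit - k1 * x[1]
        for j in range(2, n + 1):
            d[j] = k1 * (x[j - 1] - x[j])
        if track_kill:
            d[n + 1] = k1 * x[n]
        return d

    y0 = np.zeros(n_states)
    y0[0] = p.w0
    edges = _segment_edges(t[-1], breaks)
    states, _, nfev = _integrate_segments(rhs, y0, t, edges, rtol, atol)
    states = _finalize_states(states, atol)
    main = states[:, : n + 1]
    diag = {"nfev": nfev, "n_segments": len(edges) - 1, "rtol": rtol, "atol": atol}
    if track_kill:
        diag["cumulative_kill"] = states[:, -1]
    return Trajectory(t=t, states=main, model="transit", params=p.to_dict(), diagnostics=diag)


def simulate_dde(
    p: DelayParams,
    schedule: DoseSchedule,
    pk: PKParams,
    t_grid,
    *,
    conc_fn: Callable[[float], float] | None = None,
    extra_breakpoints: Sequence[float] = (),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the fixed-delay variant by the method of steps.

    History: ``x1(s) = w0`` and ``c(s) = 0`` for ``s < 0``.  Breakpoints are
    placed at every multiple of ``tau`` and at each dose time propagated
    through the lag to second order (``t_i``, ``t_i + tau``, ``t_i + 2 tau``),
    so every integration segment sees a smooth lagged term and reaches no
    further back than already-computed history.
    """
    t = _prepare_grid(t_grid)
    lam0, lam1, psi, k2, tau, w0 = p.lambda0, p.lambda1, p.psi, p.k2, p.tau, p.w0
    t_end = float(t[-1])

    if conc_fn is None:
        dose_times: list[float] = list(schedule.times)
        base_fn = _scalar_concentration(schedule, pk)
        conc_fn = lambda tt: base_fn(tt) if tt >= 0 else 0.0  # noqa: E731
    else:
        dose_times = list(extra_breakpoints)
        user_fn = conc_fn
        conc_fn = lambda tt: user_fn(tt) if tt >= 0 else 0.0  # noqa: E731

    if tau == 0.0:
        # Instantaneous removal: the damaged pool never accumulates.
        def rhs0(tt, x):
            _guard_state(x[0], x[0])
            return [lam0 * (x[0] * _growth_factor(x[0], lam0, lam1, psi)) - k2 * conc_fn(tt) * x[0]]

        edges = _segment_edges(t_end, dose_times)
        x1, _, nfev = _integrate_segments(rhs0, np.array([w0]), t, edges, rtol, atol)
        states = np.hstack([x1, np.zeros_like(x1)])
        states = _finalize_states(states, atol)
        return Trajectory(
            t=t,
            states=states,
            model="dde",
            params=p.to_dict(),
            diagnostics={"nfev": nfev, "n_segments": len(edges) - 1, "rtol": rtol, "atol": atol},
        )

    breaks: set[float] = set()
    m = 1
    while m * tau < t_end:
        breaks.add(m * tau)
        m += 1
    for td in dose_times:
        for shift in (0.0, tau, 2.0 * tau):
            breaks.add(td + shift)
    edges = _segment_edges(t_end, sorted(breaks))

    dense: list[tuple[float, float, object]] = []
    seg_ends: list[float] = []

    def x1_lag(s: float) -> float:
        if s <= 0.0:
            return w0
        i = bisect.bisect_left(seg_ends, s)
        if i >= len(dense):  # s == current segment start; use last history end
            i = len(dense) - 1
        a, b, interp = dense[i]
        return float(interp(min(max(s, a), b))[0])

    def rhs(tt, x):
        _guard_state(x[0] + x[1], x[0])
        c_now = conc_fn(tt)
        hit = k2 * c_now * x[0]
        removed = k2 * conc_fn(tt - tau) * x1_lag(tt - tau) if tt >= tau else 0.0
        w = x[0] + x[1]
        g = lam0 * (x[0] * _growth_factor(w, lam0, lam1, psi))
        return [g - hit, hit - removed]

    rhs = _budgeted(rhs)
    n_times = len(t)
    out = np.empty((n_times, 2))
    out[0] = (w0, 0.0)
    y = np.array([w0, 0.0])
    nfev = 0
    for a, b in zip(edges, edges[1:]):
        inside = t[(t > a) & (t <= b)]
        t_eval = np.unique(np.append(inside, b))
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", t_eval=t_eval, dense_output=True,
            rtol=rtol, atol=atol,
        )
        nfev += sol.nfev
        if not sol.success:
            raise SolverError(
                f"DDE integration failed on [{a}, {b}]: {sol.message}",
                last_t=float(sol.t[-1]) if len(sol.t) else a,
            )
        dense.append((a, b, sol.sol))
        seg_ends.append(b)
        for tt, yy in zip(sol.t, sol.y.T):
            idx = np.searchsorted(t, tt)
            if idx < n_times and t[idx] == tt:
                out[idx] = yy
        y = sol.y[:, -1]

    states = _finalize_states(out, atol)
    return Trajectory(
        t=t,
        states=states,
        model="dde",
        params=p.to_dict(),
        diagnostics={"nfev": nfev, "n_segments": len(edges) - 1, "rtol": rtol, "atol": atol},
    )
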