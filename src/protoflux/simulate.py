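"""Lineage simulation: integrate growth between divisions, divide, repeat.

A protocell grows by accumulating fatty acids; when the fatty-acid
count reaches the threshold ``fa_div`` (surface area at the critical
size) the cell divides and the tracked daughter inherits half the
molecules of every species — exactly half in the deterministic model,
a binomial(count, 1/2) draw per species in the stochastic variant.
Repeating the grow/divide cycle yields a lineage whose inter-division
intervals converge to a steady state; the reciprocal of the converged
interval is the per-day division rate reported throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import (ConfigurationError, ModelParams, SpeciesCounts,
                     default_initial_state)
from .rates import I_FA, I_AA1, I_AA2, I_S, I_E, I_N, NumericalStateError

__all__ = [
    "DivisionEvent",
    "Trajectory",
    "Lineage",
    "SteadyState",
    "IntegrationError",
    "step_to_division",
    "divide",
    "run_lineage",
    "steady_state_metrics",
    "division_rate",
]

DivisionMode = Literal["deterministic", "stochastic"]

#: integrator defaults; collapse-regime dynamics can be stiff, so the
#: solver is LSODA (switches to BDF automatically) with tight tolerances
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    def __init__(self, message: str, state=None, cycle: int | None = None):
        super().__init__(message)
        self.state = state
        self.cycle = cycle


@dataclass(frozen=True)
class DivisionEvent:
    time: float
    mother_counts: SpeciesCounts
    daughter_counts: SpeciesCounts
    mode: DivisionMode
    cycle: int
    rng_seed: int | None = None


@dataclass(frozen=True)
class Trajectory:
    """Dense state samples from one inter-division growth phase."""

    t: np.ndarray          # shape (m,), days
    y: np.ndarray          # shape (6, m), counts in canonical order
    reached_threshold: bool

    @property
    def final_state(self) -> SpeciesCounts:
        return SpeciesCounts.from_array(self.y[:, -1])


@dataclass
class Lineage:
    events: list[DivisionEvent] = field(default_factory=list)
    trajectories: list[Trajectory] = field(default_factory=list)
    last_cycle: Trajectory | None = None
    collapsed: bool = False

    def intervals(self) -> np.ndarray:
        """Inter-division intervals in days (first division measured
        from t=0)."""
        times = np.array([ev.time for ev in self.events])
        if times.size == 0:
            return times
        return np.diff(np.concatenate([[0.0], times]))


@dataclass(frozen=True)
class SteadyState:
    division_rate: float
    eq_concentrations: np.ndarray | None
    converged: bool
    cycles_used: int


def _make_rhs(p: ModelParams):
    """Build a fast closure for the ODE right-hand side.

    Hoists every parameter lookup out of the per-step path; kept in
    exact agreement with :func:`protoflux.rates.rhs` (tested)."""
    lam = p.lambdas()
    k_in = p.k_in_array()
    inv_nc2 = 1.0 / p.n_c2_array()
    k_fix_co2 = p.k_fix * p.co2
    k_m = p.k_m
    k_sat = p.k_sat
    k_ne = p.k_ne
    k_nn = p.k_nn
    vol_per_fa = p.vol_per_fa
    strengths_max = float(k_in.max(initial=0.0))
    kcn_eff = p.k_cn * max(0.0, 1.0 - p.alpha * strengths_max)
    any_kin = bool(np.any(k_in > 0))

    def f(t, y):
        fa = y[I_FA]
        vol = vol_per_fa * fa
        n_conc = max(y[I_N], 0.0) / vol
        rho = max(y[I_AA1], 0.0) / fa
        flux = k_fix_co2 * fa * (rho / (k_m + rho)) * (1.0 + kcn_eff * n_conc)
        if any_kin and n_conc > 0.0:
            sigma = n_conc / (k_sat + n_conc)
            w = lam / (1.0 - k_in * sigma)
            fractions = w / w.sum()
        else:
            fractions = lam
        production = flux * fractions * inv_nc2
        nuc = (k_ne * max(y[I_AA2], 0.0) * max(y[I_S], 0.0) * max(y[I_E], 0.0)
               / (vol * vol) * (1.0 + k_nn * n_conc))
        dy = np.empty(6)
        dy[:I_N] = production
        dy[I_AA2] -= nuc
        dy[I_S] -= nuc
        dy[I_E] -= nuc
        dy[I_N] = nuc
        return dy

    return f


def step_to_division(state: SpeciesCounts, p: ModelParams, t_max: float,
                     rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                     _rhs=None) -> tuple[Trajectory, DivisionEvent | None]:
    """Integrate one growth phase until fa reaches ``fa_div`` or
    ``t_max`` days elapse.

    Returns the dense trajectory and, if the threshold was reached, a
    :class:`DivisionEvent` stub (mother == final state; the daughter is
    filled in by the caller after partitioning).  A timeout returns
    ``(trajectory, None)``.
    """
    y0 = state.as_array()
    if y0[I_FA] >= p.fa_div:
        raise ConfigurationError(
            f"initial fa={y0[I_FA]} already at or above fa_div={p.fa_div}")
    f = _rhs if _rhs is not None else _make_rhs(p)

    def hit_threshold(t, y):
        return y[I_FA] - p.fa_div

    hit_threshold.terminal = True
    hit_threshold.direction = 1.0

    sol = solve_ivp(f, (0.0, t_max), y0, method="LSODA", rtol=rtol, atol=atol,
                    events=hit_threshold, dense_output=False)
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}",
                               state=sol.y[:, -1] if sol.y.size else y0)
    if sol.status == 1 and len(sol.t_events[0]) > 0:
        t_ev = float(sol.t_events[0][0])
        y_ev = sol.y_events[0][0]
        traj = Trajectory(t=np.append(sol.t, t_ev),
                          y=np.column_stack([sol.y, y_ev]),
                          reached_threshold=True)
        mother = SpeciesCounts.from_array(y_ev)
        event = DivisionEvent(time=t_ev, mother_counts=mother,
                              daughter_counts=mother, mode="deterministic",
                              cycle=-1)
        return traj, event
    return Trajectory(t=sol.t, y=sol.y, reached_threshold=False), None


def divide(state: SpeciesCounts, mode: DivisionMode = "deterministic",
           rng: np.random.Generator | None = None,
           noise: float = 1.0) -> SpeciesCounts:
    """Partition a mother cell, returning the tracked daughter.

    Deterministic mode halves every count exactly, which leaves all
    concentrations unchanged (the volume, proportional to fa, halves
    too).  Stochastic mode rounds each count to the nearest integer
    (half-to-even) and draws binomial(count, 1/2) per species
    independently; ``noise`` in [0, 1] interpolates linearly between
    exact halving (0) and the full binomial draw (1), scaling the
    segregation variance by ``noise**2``.
    """
    y = state.as_array()
    if mode == "deterministic":
        return SpeciesCounts.from_array(y / 2.0)
    if mode != "stochastic":
        raise ConfigurationError(f"unknown division mode {mode!r}")
    if rng is None:
        raise ConfigurationError("stochastic division requires an rng")
    if not 0.0 <= noise <= 1.0:
        raise ConfigurationError(f"noise must lie in [0, 1], got {noise!r}")
    m = np.rint(y)  # round-half-to-even
    draws = rng.binomial(m.astype(np.int64), 0.5).astype(float)
    daughter = m / 2.0 + noise * (draws - m / 2.0)
    return SpeciesCounts.from_array(daughter)


def run_lineage(p: ModelParams, init: SpeciesCounts | None = None,
                max_divisions: int = 200, t_budget: float = 500.0,
                mode: DivisionMode = "deterministic",
                rng: np.random.Generator | None = None,
                noise: float = 1.0,
                cycle_t_max: float = 100.0,
                rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                record_trajectories: bool = False) -> Lineage:
    """Simulate one cell line: grow to threshold, divide, follow one
    daughter; stop at ``max_divisions`` divisions, ``t_budget`` days, or
    collapse.

    A cycle that exhausts ``cycle_t_max`` days without reaching the
    division threshold marks the lineage collapsed (the cell is not
    dead, it just no longer divides on any relevant time scale).  The
    most recent completed growth phase is always kept in ``last_cycle``
    for equilibrium-concentration estimates.
    """
    state = (init if init is not None else default_initial_state(p)).validate()
    if mode == "stochastic" and rng is None:
        raise ConfigurationError("stochastic mode requires an rng")
    lineage = Lineage()
    f = _make_rhs(p)
    t_now = 0.0
    for cycle in range(max_divisions):
        remaining = t_budget - t_now
        if remaining <= 0:
            break
        t_max = min(cycle_t_max, remaining)
        try:
            traj, event = step_to_division(state, p, t_max, rtol=rtol,
                                           atol=atol, _rhs=f)
        except (IntegrationError, NumericalStateError) as err:
            raise IntegrationError(f"cycle {cycle}: {err}", state=state,
                                   cycle=cycle) from err
        if record_trajectories:
            shifted = Trajectory(t=traj.t + t_now, y=traj.y,
                                 reached_threshold=traj.reached_threshold)
            lineage.trajectories.append(shifted)
        lineage.last_cycle = traj
        if event is None:
            # timed out: collapsed only if the cell had a full window
            if t_max >= cycle_t_max - 1e-12 or not lineage.events:
                lineage.collapsed = True
            break
        t_now += event.time
        mother = event.mother_counts
        daughter = divide(mother, mode=mode, rng=rng, noise=noise)
        lineage.events.append(DivisionEvent(
            time=t_now, mother_counts=mother, daughter_counts=daughter,
            mode=mode, cycle=cycle))
        state = daughter
    return lineage


def _cycle_mean_concentrations(traj: Trajectory, p: ModelParams) -> np.ndarray:
    """Time-averaged concentrations over one growth phase (trapezoid)."""
    if traj.t.size < 2:
        vol = p.vol_per_fa * traj.y[I_FA, -1]
        return traj.y[:, -1] / vol
    conc = traj.y / (p.vol_per_fa * traj.y[I_FA])
    span = traj.t[-1] - traj.t[0]
    if span <= 0:
        return conc[:, -1]
    return np.trapezoid(conc, traj.t, axis=1) / span


def steady_state_metrics(lineage: Lineage, p: ModelParams,
                         rel_tol: float = 1e-4, k: int = 5) -> SteadyState:
    """Converged per-day division rate and equilibrium concentrations.

    Deterministic lineages are converged when the last ``k``
    inter-division intervals have relative spread below ``rel_tol``;
    the rate is the reciprocal of their mean.  Stochastic lineages never
    settle to a fixed interval, so convergence is judged on the running
    mean: after discarding the first half of the intervals as burn-in,
    the two halves of the remainder must agree within two standard
    errors.  Collapsed lineages report rate zero.
    """
    if lineage.collapsed and not lineage.events:
        return SteadyState(0.0, None, converged=False, cycles_used=0)
    intervals = lineage.intervals()
    n = intervals.size
    eq = (_cycle_mean_concentrations(lineage.last_cycle, p)
          if lineage.last_cycle is not None else None)
    if lineage.collapsed:
        return SteadyState(0.0, eq, converged=False, cycles_used=n)
    if n == 0:
        return SteadyState(0.0, None, converged=False, cycles_used=0)
    stochastic = lineage.events[-1].mode == "stochastic"
    if not stochastic:
        if n < k + 1:
            last = intervals[-min(n, k):]
            return SteadyState(1.0 / last.mean(), eq, converged=False,
                               cycles_used=n)
        last = intervals[-k:]
        spread = (last.max() - last.min()) / last.mean()
        return SteadyState(1.0 / last.mean(), eq, converged=bool(spread < rel_tol),
                           cycles_used=n)
    # stochastic: burn-in then running-mean stability
    tail = intervals[n // 2:]
    m = tail.size
    if m < 2 * k:
        return SteadyState(1.0 / tail.mean(), eq, converged=False, cycles_used=n)
    first, second = tail[: m // 2], tail[m // 2:]
    se = tail.std(ddof=1) / math.sqrt(m)
    converged = abs(first.mean() - second.mean()) < 2.0 * se + 1e-15
    return SteadyState(1.0 / tail.mean(), eq, converged=bool(converged),
                       cycles_used=n)


def division_rate(p: ModelParams, init: SpeciesCounts | None = None,
                  **lineage_kwargs) -> float:
    """Steady-state divisions per day from the default initial state.

    Convenience wrapper: run a lineage, extract the converged rate.
    Deterministic given the parameters; collapse returns 0.
    """
    lineage = run_lineage(p, init=init, **lineage_kwargs)
    return steady_state_metrics(lineage, p).division_rate
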