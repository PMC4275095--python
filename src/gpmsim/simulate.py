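"""Scenario driver: piecewise ODE integration, efficacy metrics, searches.

A scenario starts from the wild-type demographic equilibrium, applies a
:class:`~gpmsim.releases.ReleasePlan` as piecewise-constant forcing on the
adult equations, and integrates the 27-ODE system segment-by-segment between
forcing discontinuities with a stiff-capable adaptive solver.

Efficacy is always expressed through the competent-vector class: wild-type
adult females ``F_9`` relative to their pre-release equilibrium ``F_bar``.
Three summary metrics are used:

* ``long_term`` — the converged relative competent density well after
  releases end (operationalized as the trajectory endpoint with a
  convergence check over the final 30 days);
* ``minimum`` — the transient trough of the relative competent density;
* ``rel_avg`` — the time-averaged relative competent density over a window
  [t0, tf], by default from the first day of releases to one year after the
  last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import (
    ConfigurationError,
    EquilibriumSummary,
    ModelParams,
    default_tensor,
    equilibrium_state,
    wildtype_equilibrium,
)
from .genetics import GENOTYPE_NAMES, N_GENOTYPES, fitness_vector, viability_vector
from .releases import ReleasePlan, allocate_rates, phase_at, release_rates_at

RTOL = 1e-8
ATOL = 1e-10
#: negative excursions smaller than this (densities of order 1e3-1e4) are
#: solver interpolation noise and are clipped to zero; larger ones are errors
NEG_CLIP = 1e-6
#: default post-release horizon used when judging long-term outcomes (days)
LONGTERM_PAD = 3 * 365.0
#: cap on the duration of a threshold-triggered initial release phase (days)
TRIGGER_CAP = 3000.0

_F9 = 9 + 8  # index of wild-type adult females in the 27-vector


class IntegrationError(RuntimeError):
    """Raised when a segment fails to integrate or goes badly negative."""


class ConvergenceWarning(UserWarning):
    """Emitted when a long-term metric has not settled by the horizon cap."""


@dataclass
class Trajectory:
    """Dense solution of one scenario.

    ``states`` has shape (27, n) in the canonical [J, F, M] x genotype
    layout; ``events`` records forcing changes as (time, label) pairs.
    """

    times: np.ndarray
    states: np.ndarray
    events: list[tuple[float, str]]
    params: ModelParams
    plan: Optional[ReleasePlan]
    equilibrium: EquilibriumSummary

    @property
    def rel_competent(self) -> np.ndarray:
        """F_9(t) / F_bar, the relative competent-vector density."""
        return self.states[_F9] / self.equilibrium.F_bar

    def state_at_end(self) -> np.ndarray:
        return self.states[:, -1].copy()

    def to_frame(self):
        """Tidy long-format DataFrame: time_days, stage, genotype, density."""
        import pandas as pd

        stages = ["J"] * 9 + ["F"] * 9 + ["M"] * 9
        genos = list(GENOTYPE_NAMES) * 3
        records = []
        for row, stage, geno in zip(self.states, stages, genos):
            records.append(
                pd.DataFrame(
                    {
                        "time_days": self.times,
                        "stage": stage,
                        "genotype": geno,
                        "density": row,
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


@dataclass(frozen=True)
class EfficacyMetrics:
    """Summary efficacy of one scenario (all relative to F_bar)."""

    long_term: float
    minimum: float
    rel_avg: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "long_term": self.long_term,
            "minimum": self.minimum,
            "rel_avg": self.rel_avg,
            "converged": self.converged,
        }


def _make_rhs(params: ModelParams, tensor: np.ndarray, R_M: np.ndarray, R_F: np.ndarray):
    """Fast closure for one constant-forcing segment."""
    w = fitness_vector(params.fitness)
    gamma = viability_vector()
    lam, nu, mu_J, mu_F, mu_M = params.lam, params.nu, params.mu_J, params.mu_F, params.mu_M
    alpha, bexp = params.alpha, params.beta - 1.0
    half_nu = nu / 2.0

    def f(t: float, y: np.ndarray) -> np.ndarray:
        y = np.maximum(y, 0.0)
        J, F, M = y[:9], y[9:18], y[18:]
        M_tot = M.sum()
        if M_tot > 0.0:
            B = lam * w * np.einsum("m,n,mni->i", F, M / M_tot, tensor)
        else:
            B = np.zeros(N_GENOTYPES)
        J_tot = J.sum()
        dd = (alpha * J_tot) ** bexp if J_tot > 0.0 else 0.0
        dJ = B - (nu + mu_J + dd) * J
        dF = gamma * half_nu * J - mu_F * F + R_F
        dM = half_nu * J - mu_M * M + R_M
        return np.concatenate([dJ, dF, dM])

    return f


def _integrate_segment(
    params,
    tensor,
    y0,
    t0,
    t1,
    R_M,
    R_F,
    dt,
    event=None,
):
    """Integrate one constant-forcing segment; returns (times, states, t_event)."""
    f = _make_rhs(params, tensor, R_M, R_F)
    t_eval = np.arange(t0, t1, dt)
    if t_eval.size == 0 or t_eval[-1] < t1:
        t_eval = np.append(t_eval, t1)
    kwargs = {}
    if event is not None:
        kwargs["events"] = [event]
    sol = solve_ivp(
        f,
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=RTOL,
        atol=ATOL,
        **kwargs,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed on [{t0}, {t1}]: {sol.message}")
    t_event = None
    if event is not None and sol.t_events[0].size > 0:
        t_event = float(sol.t_events[0][0])
        # truncate the dense grid at the event and append the event state
        keep = sol.t < t_event
        times = np.append(sol.t[keep], t_event)
        states = np.column_stack([sol.y[:, keep], sol.y_events[0][0]])
    else:
        times, states = sol.t, sol.y
    low = states.min()
    if low < -NEG_CLIP:
        raise IntegrationError(f"state went negative ({low:.3e}) on [{t0}, {t1}]")
    states = np.maximum(states, 0.0)
    return times, states, t_event


def _release_segments(plan: ReleasePlan, M_bar: float, horizon: float):
    """Constant-forcing segments [(t0, t1, R_M, R_F, label), ...] up to horizon."""
    zeros = np.zeros(N_GENOTYPES)
    pts = [p for p in plan.breakpoints() if p < horizon] + [horizon]
    segs = []
    for t0, t1 in zip(pts[:-1], pts[1:]):
        strain = phase_at(t0, plan)
        if strain is None:
            R_M, R_F = zeros, zeros
            label = "releases_end"
        else:
            R_M, R_F = release_rates_at(t0, plan, M_bar)
            label = f"release_{GENOTYPE_NAMES[strain]}"
        segs.append((t0, t1, R_M, R_F, label))
    return segs


def run_scenario(
    params: ModelParams,
    plan: Optional[ReleasePlan],
    horizon: Optional[float] = None,
    initial="wildtype_equilibrium",
    dt: float = 0.5,
) -> Trajectory:
    """Integrate one release scenario from (by default) wild-type equilibrium.

    ``horizon`` defaults to three years past the end of releases (or past the
    maintenance horizon for plans with maintenance).  ``dt`` is the output
    grid spacing in days; the solver's own steps are adaptive.
    """
    tensor = default_tensor()
    eq = wildtype_equilibrium(params)
    if isinstance(initial, str):
        if initial != "wildtype_equilibrium":
            raise ValueError(f"unknown initial condition {initial!r}")
        y0 = equilibrium_state(params).to_vector()
    else:
        y0 = np.asarray(initial, dtype=float)

    if plan is not None and plan.maintenance is not None:
        return _run_maintenance(params, plan, eq, y0, horizon, dt)

    if plan is None or plan.r == 0.0:
        T_end = 0.0
        segs = [(0.0, horizon or LONGTERM_PAD, np.zeros(9), np.zeros(9), "no_release")]
    else:
        T_end = plan.T
        if horizon is None:
            horizon = plan.T + LONGTERM_PAD
        if horizon <= T_end:
            raise ValueError("horizon must exceed the release duration")
        segs = _release_segments(plan, eq.M_bar, horizon)

    times_all, states_all, events = [], [], []
    y = y0
    for t0, t1, R_M, R_F, label in segs:
        events.append((t0, label))
        t, ys, _ = _integrate_segment(params, tensor, y, t0, t1, R_M, R_F, dt)
        y = ys[:, -1]
        times_all.append(t if not times_all else t[1:])
        states_all.append(ys if not states_all else ys[:, 1:])
    return Trajectory(
        times=np.concatenate(times_all),
        states=np.column_stack(states_all),
        events=events,
        params=params,
        plan=plan,
        equilibrium=eq,
    )


def _phase1_to_trigger(params, plan, eq, y0, dt):
    """Integrate original-rate releases until the maintenance trigger.

    Returns (times, states, t_trigger, trigger_level).
    """
    tensor = default_tensor()
    maint = plan.maintenance
    if maint.trigger == "fixed":
        base = replace(plan, maintenance=None)
        segs = _release_segments(base, eq.M_bar, base.T)
        times_all, states_all = [], []
        y = y0
        for t0, t1, R_M, R_F, _ in segs:
            t, ys, _ = _integrate_segment(params, tensor, y, t0, t1, R_M, R_F, dt)
            y = ys[:, -1]
            times_all.append(t if not times_all else t[1:])
            states_all.append(ys if not states_all else ys[:, 1:])
        times = np.concatenate(times_all)
        states = np.column_stack(states_all)
        return times, states, plan.T, states[_F9, -1] / eq.F_bar

    theta = maint.theta

    def crossing(t, y):
        return y[_F9] / eq.F_bar - theta

    crossing.terminal = True
    crossing.direction = -1.0

    # phase-1 forcing: the plan's schedule with the release window held open
    # until the trigger (combination plans still switch strains at T_s)
    pts = [0.0] + ([plan.T_s] if plan.is_combination else [])
    pts = [p for p in pts if p < TRIGGER_CAP] + [TRIGGER_CAP]
    times_all, states_all = [], []
    y = y0
    t_trig = None
    for t0, t1 in zip(pts[:-1], pts[1:]):
        strain = phase_at(min(t0, plan.T - 1e-9), plan)
        R_M, R_F = allocate_rates(strain, plan.r * eq.M_bar / 7.0, plan.female_fraction)
        t, ys, t_event = _integrate_segment(
            params, tensor, y, t0, t1, R_M, R_F, dt, event=crossing
        )
        y = ys[:, -1]
        times_all.append(t if not times_all else t[1:])
        states_all.append(ys if not states_all else ys[:, 1:])
        if t_event is not None:
            t_trig = t_event
            break
    if t_trig is None:
        raise ConfigurationError(
            f"relative competent density never fell to theta={theta} within "
            f"{TRIGGER_CAP} days; threshold unreachable for this plan"
        )
    times = np.concatenate(times_all)
    states = np.column_stack(states_all)
    return times, states, t_trig, states[_F9, -1] / eq.F_bar


def _run_maintenance(params, plan, eq, y0, horizon, dt):
    tensor = default_tensor()
    maint = plan.maintenance
    times, states, t_trig, _level = _phase1_to_trigger(params, plan, eq, y0, dt)
    events = [(0.0, f"release_{GENOTYPE_NAMES[phase_at(0.0, plan)]}")]
    if plan.is_combination and t_trig > plan.T_s:
        events.append((plan.T_s, f"release_{GENOTYPE_NAMES[phase_at(plan.T_s, plan)]}"))
    events.append((t_trig, "maintenance_start"))

    t_end = t_trig + maint.horizon if horizon is None else horizon
    strain = plan.maintenance_strain
    R_M, R_F = allocate_rates(
        strain, maint.r_p * plan.r * eq.M_bar / 7.0, plan.female_fraction
    )
    t2, s2, _ = _integrate_segment(
        params, tensor, states[:, -1], t_trig, t_end, R_M, R_F, dt
    )
    return Trajectory(
        times=np.concatenate([times, t2[1:]]),
        states=np.column_stack([states, s2[:, 1:]]),
        events=events,
        params=params,
        plan=plan,
        equilibrium=eq,
    )


def relative_average_density(
    traj: Trajectory,
    t0: float = 0.0,
    tf: Optional[float] = None,
    F_bar: Optional[float] = None,
) -> float:
    """Time-averaged relative competent density over [t0, tf].

    ``tf`` defaults to one year past the end of releases.  Composite
    trapezoidal quadrature on the dense output grid.
    """
    if tf is None:
        if traj.plan is None:
            raise ValueError("tf must be given for a plan-free trajectory")
        tf = traj.plan.T + 365.0
    if F_bar is None:
        F_bar = traj.equilibrium.F_bar
    if t0 >= tf:
        raise ValueError("need t0 < tf")
    if t0 < traj.times[0] - 1e-9 or tf > traj.times[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {tf}] outside trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    mask = (traj.times >= t0) & (traj.times <= tf)
    t = traj.times[mask]
    f = traj.states[_F9, mask] / F_bar
    return float(np.trapezoid(f, t) / (tf - t0))


def minimum_density(traj: Trajectory) -> float:
    """Trough of the relative competent density over the run."""
    return float(traj.rel_competent.min())


def long_term_density(traj: Trajectory, rel_tol: float = 1e-5) -> float:
    """Relative competent density at the end of the run, convergence-checked.

    Convergence means the relative change of F_9/F_bar over the final 30 days
    is below ``rel_tol``; densities below 1e-10 count as eliminated.  A
    non-converged endpoint is returned with a :class:`ConvergenceWarning`.
    """
    f = traj.rel_competent
    t = traj.times
    if traj.plan is not None and t[-1] < traj.plan.T + 730.0 - 1e-6:
        warnings.warn(
            "trajectory ends less than two years after releases; long-term "
            "value may not be settled",
            ConvergenceWarning,
            stacklevel=2,
        )
    end = f[-1]
    if end < 1e-10:
        return float(end)
    i30 = np.searchsorted(t, t[-1] - 30.0)
    change = abs(end - f[i30]) / max(end, 1e-300)
    if change >= rel_tol:
        warnings.warn(
            f"long-term density not converged: relative change {change:.2e} "
            "over the final 30 days",
            ConvergenceWarning,
            stacklevel=2,
        )
    return float(end)


def converged_long_term(
    params: ModelParams,
    plan: ReleasePlan,
    dt: float = 0.5,
    max_horizon: float = 15 * 365.0,
) -> tuple[float, bool]:
    """Long-term relative competent density, extending the horizon if needed.

    Reruns with a doubled post-release pad until the endpoint is converged or
    the horizon cap is reached; returns (value, converged_flag).
    """
    pad = LONGTERM_PAD
    while True:
        traj = run_scenario(params, plan, horizon=plan.T + pad, dt=dt)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            value = long_term_density(traj)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        if converged or plan.T + 2 * pad > max_horizon:
            if not converged:
                warnings.warn(
                    f"long-term density for {plan.strategy} not converged at "
                    f"horizon cap {plan.T + pad:.0f} d",
                    ConvergenceWarning,
                    stacklevel=2,
                )
            return value, converged
        pad *= 2.0


def metrics(traj: Trajectory, t0: float = 0.0, tf: Optional[float] = None) -> EfficacyMetrics:
    """All three efficacy summaries of a trajectory.

    The averaging window defaults to release start through one year after
    the last release, clamped to the trajectory span for short runs.
    """
    if tf is None:
        end = float(traj.times[-1])
        tf = end if traj.plan is None else min(traj.plan.T + 365.0, end)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        lt = long_term_density(traj)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return EfficacyMetrics(
        long_term=lt,
        minimum=minimum_density(traj),
        rel_avg=relative_average_density(traj, t0=t0, tf=tf),
        converged=converged,
    )


def rank_strategies(
    params: ModelParams,
    plans: Sequence[ReleasePlan],
    metric: str = "long_term",
    dt: float = 0.5,
    tie_tol: float = 1e-9,
) -> list[dict]:
    """Order release plans from most to least effective under one metric.

    Most effective = lowest competent-vector metric.  Returns a list of dicts
    with keys ``strategy``, ``value``, ``margin`` (gap to the next-better
    plan; 0 for the best) and ``tied_with_previous``.
    """
    if metric not in ("long_term", "minimum", "rel_avg"):
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for plan in plans:
        if metric == "long_term":
            value, _ = converged_long_term(params, plan, dt=dt)
        else:
            traj = run_scenario(params, plan, dt=dt)
            value = minimum_density(traj) if metric == "minimum" else relative_average_density(traj)
        rows.append({"strategy": plan.strategy, "value": value})
    rows.sort(key=lambda r: r["value"])
    out = []
    for k, row in enumerate(rows):
        margin = 0.0 if k == 0 else row["value"] - rows[k - 1]["value"]
        scale = max(abs(row["value"]), 1e-300)
        out.append(
            {
                **row,
                "margin": margin,
                "tied_with_previous": k > 0 and margin / scale < tie_tol,
            }
        )
    return out


_AXES = ("c_A", "beta", "phi", "T_s")


def _apply_axis(axis: str, x: float, params: ModelParams, plan: ReleasePlan):
    if axis == "c_A":
        return params.with_(c_A=x), plan
    if axis == "beta":
        return params.with_(beta=x), plan
    if axis == "phi":
        return params, replace(plan, sex_mode=float(x))
    if axis == "T_s":
        return params, replace(plan, T_s=float(x))
    raise ValueError(f"unknown axis {axis!r}; expected one of {_AXES}")


def find_crossover(
    axis: str,
    pair: tuple[ReleasePlan, ReleasePlan],
    metric: str,
    bracket: tuple[float, float],
    params: Optional[ModelParams] = None,
    xtol: float = 1e-3,
    dt: float = 0.5,
) -> Optional[float]:
    """Parameter value at which two plans' efficacy metrics are equal.

    Bisection on the deterministic metric difference over ``bracket``;
    returns ``None`` when the difference does not change sign (no crossover).
    """
    if params is None:
        params = ModelParams()
    plan_a, plan_b = pair

    def diff(x: float) -> float:
        total = 0.0
        for sign, plan in ((1.0, plan_a), (-1.0, plan_b)):
            p, pl = _apply_axis(axis, x, params, plan)
            if metric == "long_term":
                v, _ = converged_long_term(p, pl, dt=dt)
            elif metric == "rel_avg":
                traj = run_scenario(p, pl, horizon=pl.T + 365.0, dt=dt)
                v = relative_average_density(traj, 0.0, pl.T + 365.0)
            else:
                raise ValueError(f"unsupported crossover metric {metric!r}")
            total += sign * v
        return total

    lo, hi = bracket
    d_lo, d_hi = diff(lo), diff(hi)
    if d_lo == 0.0 and d_hi == 0.0:
        return None
    if d_lo * d_hi > 0.0:
        return None
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        d_mid = diff(mid)
        if d_mid == 0.0:
            return mid
        if d_lo * d_mid < 0.0:
            hi, d_hi = mid, d_mid
        else:
            lo, d_lo = mid, d_mid
    return 0.5 * (lo + hi)


def sustained_release_plateau(
    params: ModelParams,
    strategy: str = "FK",
    r: float = 1.0,
    sex_mode="male_only",
    t_hold: float = 600.0,
    dt: float = 0.5,
) -> float:
    """Relative competent density reached under indefinitely sustained releases.

    Integrates a single-strain release held for ``t_hold`` days and returns
    the endpoint; used, e.g., to find the lowest density FK-only releases can
    hold the population at — the natural common threshold when comparing
    maintenance programmes across strategies.
    """
    plan = ReleasePlan(strategy=strategy, r=r, T=t_hold, sex_mode=sex_mode)
    traj = run_scenario(params, plan, horizon=t_hold + 1.0, dt=dt)
    i = np.searchsorted(traj.times, t_hold)
    return float(traj.rel_competent[i])


def recovery_occurs(
    params: ModelParams,
    plan: ReleasePlan,
    rel_tol: float = 1e-6,
    dt: float = 0.5,
) -> bool:
    """Whether the competent-vector density recovers under maintenance.

    Recovery = the relative competent density exceeding its trigger-time
    level at any time within the maintenance horizon.
    """
    if plan.maintenance is None:
        raise ValueError("plan has no maintenance phase")
    traj = run_scenario(params, plan, dt=dt)
    t_trig = next(t for t, label in traj.events if label == "maintenance_start")
    i_trig = np.searchsorted(traj.times, t_trig)
    f = traj.rel_competent
    level = f[i_trig]
    return bool(f[i_trig:].max() > level * (1.0 + rel_tol))


def minimal_maintenance_fraction(
    params: ModelParams,
    plan: ReleasePlan,
    resolution: float = 0.01,
    dt: float = 0.5,
) -> Optional[float]:
    """Smallest maintenance fraction r_p preventing competent-vector recovery.

    Bisection on the r_p grid of the given resolution; returns ``None`` when
    even r_p = 1 (full original ratio) fails to prevent recovery.
    """
    if plan.maintenance is None:
        raise ValueError("plan has no maintenance phase")
    n = int(round(1.0 / resolution))

    def ok(k: int) -> bool:
        rp = k / n
        trial = replace(plan, maintenance=replace(plan.maintenance, r_p=rp))
        return not recovery_occurs(params, trial, dt=dt)

    if not ok(n):
        return None
    if ok(0):
        return 0.0
    lo, hi = 0, n  # ok(lo) False, ok(hi) True
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi / n
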