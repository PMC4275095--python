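"""Continuous-time Markov-chain analog of the deterministic model.

Each term of the 27-ODE system becomes an event channel on integer counts:

* birth of a genotype-*i* juvenile at rate ``B_i`` (the offspring genotype is
  already marginalized into the per-genotype birth rates);
* juvenile death of class *i* at rate ``(mu_J + (alpha J_tot)^(beta-1)) J_i``;
* emergence from class *i* at rate ``nu J_i`` — the emerging adult is male
  with probability 1/2, and an emerging female survives with probability
  ``gamma_i`` (FK lethality);
* adult deaths at rates ``mu_F F_i`` and ``mu_M M_i``;
* releases as Poisson arrivals at the deterministic forcing rates.

Two integrators are provided: the exact Gillespie stochastic simulation
algorithm (default) and a fixed-step tau-leaping scheme vectorized across
replicates for population-scale runs.  The construction is the canonical
event-per-term analog of the deterministic system; the demographic rates and
the mean-field limit are shared with :mod:`gpmsim.dynamics` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import ModelParams, default_tensor, equilibrium_state, wildtype_equilibrium
from .genetics import N_GENOTYPES, fitness_vector, viability_vector
from .releases import ReleasePlan, release_rates_at

_F9 = 9 + 8


@dataclass
class StochasticState:
    """Integer counts for the 27 classes."""

    J: np.ndarray
    F: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.int64)
        self.F = np.asarray(self.F, dtype=np.int64)
        self.M = np.asarray(self.M, dtype=np.int64)

    @classmethod
    def from_equilibrium(cls, params: ModelParams) -> "StochasticState":
        s = equilibrium_state(params)
        return cls(np.rint(s.J), np.rint(s.F), np.rint(s.M))

    def total(self) -> int:
        return int(self.J.sum() + self.F.sum() + self.M.sum())


def scale_population(params: ModelParams, scale: float) -> ModelParams:
    """Rescale the equilibrium population size without changing per-capita rates.

    The equilibrium density is proportional to 1/alpha, so dividing alpha by
    ``scale`` multiplies all equilibrium class sizes by ``scale``.  Useful
    for running the exact SSA on small populations.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return params.with_(alpha=params.alpha / scale)


def event_rates(
    state: StochasticState,
    params: ModelParams,
    tensor: np.ndarray,
    R_M: Optional[np.ndarray] = None,
    R_F: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Per-channel event rates at the given state (the rate catalogue).

    Returns a dict of 9-vectors keyed by channel family: ``birth``,
    ``juvenile_death``, ``emergence``, ``female_death``, ``male_death``,
    ``release_M``, ``release_F``.  Rates mirror the deterministic model
    term-by-term.
    """
    J = state.J.astype(float)
    F = state.F.astype(float)
    M = state.M.astype(float)
    M_tot = M.sum()
    w = fitness_vector(params.fitness)
    if M_tot > 0.0:
        B = params.lam * w * np.einsum("m,n,mni->i", F, M / M_tot, tensor)
    else:
        B = np.zeros(N_GENOTYPES)
    J_tot = J.sum()
    dd = (params.alpha * J_tot) ** (params.beta - 1.0) if J_tot > 0 else 0.0
    zeros = np.zeros(N_GENOTYPES)
    return {
        "birth": B,
        "juvenile_death": (params.mu_J + dd) * J,
        "emergence": params.nu * J,
        "female_death": params.mu_F * F,
        "male_death": params.mu_M * M,
        "release_M": zeros if R_M is None else np.asarray(R_M, dtype=float),
        "release_F": zeros if R_F is None else np.asarray(R_F, dtype=float),
    }


def total_event_rate(rates: dict[str, np.ndarray]) -> float:
    return float(sum(v.sum() for v in rates.values()))


_CHANNELS = (
    "birth",
    "juvenile_death",
    "emergence",
    "female_death",
    "male_death",
    "release_M",
    "release_F",
)


def _forcing_segments(plan: Optional[ReleasePlan], M_bar: float, horizon: float):
    zeros = np.zeros(N_GENOTYPES)
    if plan is None or plan.r == 0.0:
        return [(0.0, horizon, zeros, zeros)]
    if plan.maintenance is not None:
        raise NotImplementedError(
            "maintenance plans are not supported by the stochastic integrators"
        )
    pts = [p for p in plan.breakpoints() if p < horizon] + [horizon]
    segs = []
    for t0, t1 in zip(pts[:-1], pts[1:]):
        if t0 < plan.T:
            R_M, R_F = release_rates_at(t0, plan, M_bar)
        else:
            R_M, R_F = zeros, zeros
        segs.append((t0, t1, R_M, R_F))
    return segs


def _gillespie_one(params, tensor, segments, record_times, y0, rng):
    gamma = viability_vector()
    state = StochasticState(y0[:9].copy(), y0[9:18].copy(), y0[18:].copy())
    out = np.zeros((27, record_times.size))
    rec = 0
    t = 0.0
    for t0, t1, R_M, R_F in segments:
        t = max(t, t0)
        while t < t1:
            rates = event_rates(state, params, tensor, R_M, R_F)
            flat = np.concatenate([rates[c] for c in _CHANNELS])
            total = flat.sum()
            if total <= 0.0:
                t = t1  # absorbing (extinct, no forcing)
                break
            t_next = t + rng.exponential(1.0 / total)
            while rec < record_times.size and record_times[rec] < min(t_next, t1):
                out[:9, rec], out[9:18, rec], out[18:, rec] = state.J, state.F, state.M
                rec += 1
            if t_next >= t1:
                t = t1
                break
            t = t_next
            cum = np.cumsum(flat)
            k = int(np.searchsorted(cum, rng.random() * total, side="right"))
            k = min(k, flat.size - 1)
            fam, i = _CHANNELS[k // 9], k % 9
            if fam == "birth":
                state.J[i] += 1
            elif fam == "juvenile_death":
                state.J[i] -= 1
            elif fam == "emergence":
                state.J[i] -= 1
                if rng.random() < 0.5:
                    state.M[i] += 1
                elif gamma[i] > 0:
                    state.F[i] += 1
            elif fam == "female_death":
                state.F[i] -= 1
            elif fam == "male_death":
                state.M[i] -= 1
            elif fam == "release_M":
                state.M[i] += 1
            else:
                state.F[i] += 1
    while rec < record_times.size:
        out[:9, rec], out[9:18, rec], out[18:, rec] = state.J, state.F, state.M
        rec += 1
    return out


def _tau_leap(params, tensor, segments, record_times, y0, rng, n_reps, tau):
    """Fixed-step tau-leaping, vectorized across replicates."""
    gamma = viability_vector()
    w = fitness_vector(params.fitness)
    J = np.tile(y0[:9], (n_reps, 1)).astype(float)
    F = np.tile(y0[9:18], (n_reps, 1)).astype(float)
    M = np.tile(y0[18:], (n_reps, 1)).astype(float)
    out = np.zeros((n_reps, 27, record_times.size))
    rec = 0
    t = 0.0
    for t0, t1, R_M, R_F in segments:
        n_steps = max(1, int(np.ceil((t1 - t0) / tau)))
        dt = (t1 - t0) / n_steps
        for _ in range(n_steps):
            while rec < record_times.size and record_times[rec] <= t + 1e-12:
                out[:, :9, rec], out[:, 9:18, rec], out[:, 18:, rec] = J, F, M
                rec += 1
            M_tot = M.sum(axis=1, keepdims=True)
            mate = np.divide(M, M_tot, out=np.zeros_like(M), where=M_tot > 0)
            B = params.lam * w * np.einsum("rm,rn,mni->ri", F, mate, tensor)
            J_tot = J.sum(axis=1, keepdims=True)
            dd = np.where(J_tot > 0, (params.alpha * J_tot) ** (params.beta - 1.0), 0.0)
            births = rng.poisson(B * dt)
            jdeaths = rng.poisson((params.mu_J + dd) * J * dt)
            emerg = rng.poisson(params.nu * J * dt)
            males = rng.binomial(emerg, 0.5)
            females = (emerg - males) * gamma.astype(np.int64)
            fdeaths = rng.poisson(params.mu_F * F * dt)
            mdeaths = rng.poisson(params.mu_M * M * dt)
            rel_m = rng.poisson(np.tile(R_M * dt, (n_reps, 1)))
            rel_f = rng.poisson(np.tile(R_F * dt, (n_reps, 1)))
            J = np.maximum(J + births - jdeaths - emerg, 0.0)
            F = np.maximum(F + females - fdeaths + rel_f, 0.0)
            M = np.maximum(M + males - mdeaths + rel_m, 0.0)
            t += dt
    while rec < record_times.size:
        out[:, :9, rec], out[:, 9:18, rec], out[:, 18:, rec] = J, F, M
        rec += 1
    return out


@dataclass
class SSAResult:
    """Replicate trajectories and cross-replicate summaries."""

    times: np.ndarray
    states: np.ndarray           # (n_reps, 27, n_times)
    params: ModelParams
    plan: Optional[ReleasePlan]
    F_bar: float
    seed: int

    @property
    def n_reps(self) -> int:
        return self.states.shape[0]

    @property
    def rel_competent(self) -> np.ndarray:
        """(n_reps, n_times) relative competent-vector density."""
        return self.states[:, _F9, :] / self.F_bar

    def summary(self) -> dict:
        """Mean, sd, quantiles of rel_competent and extinction frequency."""
        rc = self.rel_competent
        totals = self.states.sum(axis=1)
        return {
            "n_reps": self.n_reps,
            "mean": rc.mean(axis=0),
            "sd": rc.std(axis=0, ddof=1) if self.n_reps > 1 else np.zeros(rc.shape[1]),
            "q05": np.quantile(rc, 0.05, axis=0),
            "q95": np.quantile(rc, 0.95, axis=0),
            "extinct_fraction": float((totals[:, -1] == 0).mean()),
        }

    def to_frame(self):
        """Tidy DataFrame: replicate, time_days, stage, genotype, count."""
        import pandas as pd

        from .genetics import GENOTYPE_NAMES

        stages = ["J"] * 9 + ["F"] * 9 + ["M"] * 9
        genos = list(GENOTYPE_NAMES) * 3
        frames = []
        for rep in range(self.n_reps):
            for k, (stage, geno) in enumerate(zip(stages, genos)):
                frames.append(
                    pd.DataFrame(
                        {
                            "replicate": rep,
                            "time_days": self.times,
                            "stage": stage,
                            "genotype": geno,
                            "count": self.states[rep, k, :],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def simulate_ssa(
    params: ModelParams,
    plan: Optional[ReleasePlan],
    horizon: float,
    n_reps: int = 1,
    seed: int = 0,
    method: str = "gillespie",
    tau: float = 0.01,
    record_dt: float = 1.0,
    initial: Optional[StochasticState] = None,
) -> SSAResult:
    """Simulate the CTMC analog; reproducible given ``seed``.

    ``method`` is ``"gillespie"`` (exact, one replicate at a time) or
    ``"tau"`` (fixed-step tau-leaping with step ``tau`` <= 0.01 days,
    vectorized across replicates — use this at population scale).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method not in ("gillespie", "tau"):
        raise ValueError(f"unknown method {method!r}")
    if method == "tau" and tau > 0.01:
        raise ValueError("tau-leap step must be <= 0.01 days")
    tensor = default_tensor()
    if initial is None:
        initial = StochasticState.from_equilibrium(params)
        F_bar = wildtype_equilibrium(params).F_bar
    else:
        # reference density for rel_competent: the equilibrium if it exists,
        # else the initial female count (subcritical test populations)
        try:
            F_bar = wildtype_equilibrium(params).F_bar
        except Exception:
            F_bar = max(float(initial.F.sum()), 1.0)
    y0 = np.concatenate([initial.J, initial.F, initial.M]).astype(np.int64)
    record_times = np.arange(0.0, horizon + record_dt / 2, record_dt)
    if plan is not None and plan.r > 0.0:
        segments = _forcing_segments(plan, wildtype_equilibrium(params).M_bar, horizon)
    else:
        segments = _forcing_segments(None, 1.0, horizon)

    if method == "tau":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        states = _tau_leap(
            params, tensor, segments, record_times, y0, rng, n_reps, tau
        )
    else:
        child_seeds = np.random.SeedSequence(seed).spawn(n_reps)
        reps = [
            _gillespie_one(
                params, tensor, segments, record_times, y0,
                np.random.default_rng(s),
            )
            for s in child_seeds
        ]
        states = np.stack(reps)
    return SSAResult(
        times=record_times,
        states=states,
        params=params,
        plan=plan,
        F_bar=F_bar,
        seed=seed,
    )
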