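"""Deterministic core: birth rates, the 27-equation ODE system, equilibrium.

State layout: 27 densities ordered ``[J_1..J_9, F_1..F_9, M_1..M_9]`` —
juveniles, adult females, adult males by genotype in the canonical order.

Model structure
---------------
Females of genotype ``m`` mate at random, with mate genotype ``n`` chosen in
proportion to the male genotype frequency ``M_n / M_tot``.  Viable larvae of
genotype ``i`` are produced at rate

    B_i = lambda * w_i * sum_{m,n} F_m * (M_n / M_tot) * Pr(i | m, n)

(egg production is implicit; the fitness cost w_i acts on the fraction of
eggs surviving to the larval stage).  Juveniles die at density-independent
rate mu_J plus density-dependent rate (alpha * J_tot)^(beta - 1) where J_tot
is the *total* juvenile density, and emerge at rate nu with a 1:1 sex ratio;
female emergence is scaled by the viability coefficient gamma_i.  Adults die
at rates mu_F and mu_M and may be supplemented by release forcing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetics import (
    N_GENOTYPES,
    FitnessSpec,
    build_inheritance_tensor,
    fitness_vector,
    viability_vector,
)

N_STATE = 3 * N_GENOTYPES


class ConfigurationError(ValueError):
    """Raised for parameter sets that violate model preconditions."""


@dataclass(frozen=True)
class ModelParams:
    """Demographic and density-dependence parameters.

    Defaults are the baseline *Aedes aegypti* parameterization used
    throughout: daily per-capita rates, with alpha a numeric scale for the
    density-dependent juvenile mortality term (alpha * J_tot)^(beta - 1).
    """

    mu_J: float = 0.03    # juvenile density-independent mortality, day^-1
    mu_F: float = 0.10    # adult female mortality, day^-1
    mu_M: float = 0.28    # adult male mortality, day^-1
    lam: float = 8.0      # larval production per female, day^-1
    nu: float = 0.14      # emergence rate, day^-1
    alpha: float = 2e-4   # density-dependence scale
    beta: float = 3.4     # density-dependence strength (dimensionless)
    fitness: FitnessSpec = field(default_factory=FitnessSpec)

    def __post_init__(self) -> None:
        for name in ("mu_J", "mu_F", "mu_M", "nu", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.lam < 0:
            raise ConfigurationError("lam must be nonnegative")
        if self.beta <= 1:
            raise ConfigurationError(
                "beta must exceed 1 (density-dependent mortality must increase with density)"
            )

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (c_A/c_K reach into fitness)."""
        fit = self.fitness
        c_A = kwargs.pop("c_A", None)
        c_K = kwargs.pop("c_K", None)
        if c_A is not None or c_K is not None:
            fit = FitnessSpec(
                c_K=fit.c_K if c_K is None else c_K,
                c_A=fit.c_A if c_A is None else c_A,
            )
            kwargs["fitness"] = fit
        return replace(self, **kwargs)


@dataclass
class PopulationState:
    """Densities of the 27 classes: juveniles, females, males by genotype."""

    J: np.ndarray
    F: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        for arr in (self.J, self.F, self.M):
            if arr.shape != (N_GENOTYPES,):
                raise ValueError("J, F, M must each be 9-vectors")

    @classmethod
    def zeros(cls) -> "PopulationState":
        return cls(np.zeros(N_GENOTYPES), np.zeros(N_GENOTYPES), np.zeros(N_GENOTYPES))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "PopulationState":
        y = np.asarray(y, dtype=float)
        return cls(y[:9], y[9:18], y[18:27])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.J, self.F, self.M])


@dataclass(frozen=True)
class EquilibriumSummary:
    """Wild-type demographic equilibrium (transgene-free)."""

    J_star: float
    F_bar: float
    M_bar: float


def birth_rates(
    state: PopulationState, params: ModelParams, tensor: np.ndarray
) -> np.ndarray:
    """Per-genotype rates B_i at which females produce viable larvae.

    With no males present there is no mating, hence no births.
    """
    M_tot = state.M.sum()
    if M_tot <= 0.0:
        return np.zeros(N_GENOTYPES)
    mate_freq = state.M / M_tot
    w = fitness_vector(params.fitness)
    # sum_{m,n} F_m mate_freq_n p[m,n,i]
    cross = np.einsum("m,n,mni->i", state.F, mate_freq, tensor)
    return params.lam * w * cross


def density_dependent_rate(J_tot: float, params: ModelParams) -> float:
    """Per-capita density-dependent juvenile mortality (alpha*J_tot)^(beta-1)."""
    if J_tot < 0:
        raise ValueError(f"total juvenile density must be nonnegative, got {J_tot}")
    if J_tot == 0.0:
        return 0.0
    return (params.alpha * J_tot) ** (params.beta - 1.0)


def rhs(
    t: float,
    y: np.ndarray,
    params: ModelParams,
    tensor: np.ndarray,
    release_forcing=None,
) -> np.ndarray:
    """Time derivative of the 27-vector state.

    ``release_forcing(t) -> (R_M, R_F)`` supplies per-genotype adult release
    rates in individuals/day; ``None`` means no releases.
    """
    state = PopulationState.from_vector(np.maximum(y, 0.0))
    B = birth_rates(state, params, tensor)
    J_tot = state.J.sum()
    dd = density_dependent_rate(J_tot, params)
    gamma = viability_vector()

    dJ = B - (params.nu + params.mu_J + dd) * state.J
    dF = gamma * (params.nu / 2.0) * state.J - params.mu_F * state.F
    dM = (params.nu / 2.0) * state.J - params.mu_M * state.M
    if release_forcing is not None:
        R_M, R_F = release_forcing(t)
        dF = dF + R_F
        dM = dM + R_M
    return np.concatenate([dJ, dF, dM])


def wildtype_equilibrium(params: ModelParams) -> EquilibriumSummary:
    """Closed-form positive equilibrium of the transgene-free model.

    Setting the wild-type equations to zero gives
    ``(alpha J*)^(beta-1) = lam*nu/(2 mu_F) - nu - mu_J`` and hence
    ``J* = (1/alpha) * (lam*nu/(2 mu_F) - nu - mu_J)^(1/(beta-1))``,
    ``F_bar = nu J* / (2 mu_F)``, ``M_bar = nu J* / (2 mu_M)``.
    """
    surplus = params.lam * params.nu / (2.0 * params.mu_F) - params.nu - params.mu_J
    if surplus <= 0:
        raise ConfigurationError(
            "no positive equilibrium: requires lam*nu/(2*mu_F) > nu + mu_J "
            f"({params.lam * params.nu / (2 * params.mu_F):.4g} <= "
            f"{params.nu + params.mu_J:.4g})"
        )
    J_star = surplus ** (1.0 / (params.beta - 1.0)) / params.alpha
    F_bar = params.nu * J_star / (2.0 * params.mu_F)
    M_bar = params.nu * J_star / (2.0 * params.mu_M)
    return EquilibriumSummary(J_star=J_star, F_bar=F_bar, M_bar=M_bar)


def equilibrium_state(params: ModelParams) -> PopulationState:
    """Wild-type equilibrium as a full 27-class state (transgenics zero)."""
    eq = wildtype_equilibrium(params)
    state = PopulationState.zeros()
    state.J[-1] = eq.J_star
    state.F[-1] = eq.F_bar
    state.M[-1] = eq.M_bar
    return state


_DEFAULT_TENSOR: np.ndarray | None = None


def default_tensor() -> np.ndarray:
    """Module-level cached inheritance tensor (it is parameter-free)."""
    global _DEFAULT_TENSOR
    if _DEFAULT_TENSOR is None:
        _DEFAULT_TENSOR = build_inheritance_tensor()
    return _DEFAULT_TENSOR
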