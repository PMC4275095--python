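"""Release strategies: strains, schedules, sex composition, maintenance.

Six strategies are supported: the single-strain programmes FK (homozygous
female-killing strain KKaa), AP (homozygous antipathogen strain kkAA) and RR
(reduce-and-replace strain KKAA, homozygous for both transgenes), plus the
combination programmes FK_AP, RR_AP and FK_RR that switch from the first
strain to the second at time ``T_s``.

Releases are continuous at total daily rate ``r * M_bar / 7`` (``r`` is the
weekly release ratio relative to the wild-type equilibrium male density
``M_bar``), held constant over the programme regardless of how the target
population responds.  The sex composition allocates this total between adult
males and adult females; comparisons across compositions are equal-effort
(the same total number of individuals released).  FK-strain females are
competent vectors, so any female allocation of the KKaa strain is reassigned
to males; AP and R&R females carry the antipathogen gene and are releasable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .genetics import IDX_AP, IDX_FK, IDX_RR, N_GENOTYPES

#: strategy name -> (first-phase strain, second-phase strain or None)
STRATEGY_PHASES: dict[str, tuple[int, Optional[int]]] = {
    "FK": (IDX_FK, None),
    "AP": (IDX_AP, None),
    "RR": (IDX_RR, None),
    "FK_AP": (IDX_FK, IDX_AP),
    "RR_AP": (IDX_RR, IDX_AP),
    "FK_RR": (IDX_FK, IDX_RR),
}

STRATEGIES = tuple(STRATEGY_PHASES)

_SEX_MODE_PHI = {"male_only": 0.0, "bisex": 0.5, "female_only": 1.0}


class PlanError(ValueError):
    """Raised for inconsistent release plans."""


@dataclass(frozen=True)
class MaintenancePlan:
    """Ongoing reduced-rate releases after an initial control phase.

    The initial phase runs either for a fixed duration (``trigger="fixed"``,
    using the plan's ``T``) or until the relative competent-vector density
    first falls to the threshold ``theta`` (``trigger="threshold"``).
    Maintenance then continues indefinitely at fraction ``r_p`` of the
    original release ratio, simulated for ``horizon`` further days.
    """

    trigger: str = "threshold"      # "threshold" | "fixed"
    theta: float = 0.5              # relative competent density threshold
    r_p: float = 0.5                # fraction of original release ratio
    horizon: float = 730.0          # days simulated past the trigger

    def __post_init__(self) -> None:
        if self.trigger not in ("threshold", "fixed"):
            raise PlanError(f"unknown maintenance trigger {self.trigger!r}")
        if not 0.0 <= self.r_p <= 1.0:
            raise PlanError("r_p must lie in [0, 1]")
        if self.trigger == "threshold" and not 0.0 < self.theta < 1.0:
            raise PlanError("theta must lie in (0, 1)")
        if self.horizon <= 0:
            raise PlanError("maintenance horizon must be positive")


@dataclass(frozen=True)
class ReleasePlan:
    """A release programme: strategy, effort, schedule and sex composition.

    ``sex_mode`` is one of ``"male_only"``, ``"bisex"``, ``"female_only"`` or
    a float female fraction phi in [0, 1].
    """

    strategy: str = "AP"
    r: float = 1.0                  # weekly release ratio (x equilibrium males)
    T: float = 100.0                # release duration, days
    T_s: float = 50.0               # switch time for combination strategies, days
    sex_mode: Union[str, float] = "male_only"
    maintenance: Optional[MaintenancePlan] = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_PHASES:
            raise PlanError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.r < 0:
            raise PlanError("release ratio r must be nonnegative")
        if self.T <= 0:
            raise PlanError("release duration T must be positive")
        if self.is_combination and not 0.0 < self.T_s < self.T:
            raise PlanError(
                f"combination strategy requires 0 < T_s < T, got T_s={self.T_s}, T={self.T}"
            )
        phi = self.female_fraction  # validates sex_mode
        if not 0.0 <= phi <= 1.0:
            raise PlanError(f"female fraction must lie in [0, 1], got {phi}")

    @property
    def is_combination(self) -> bool:
        return STRATEGY_PHASES[self.strategy][1] is not None

    @property
    def female_fraction(self) -> float:
        if isinstance(self.sex_mode, str):
            try:
                return _SEX_MODE_PHI[self.sex_mode]
            except KeyError:
                raise PlanError(f"unknown sex_mode {self.sex_mode!r}") from None
        return float(self.sex_mode)

    @property
    def maintenance_strain(self) -> int:
        """Strain used for maintenance: the strain active as releases end."""
        first, second = STRATEGY_PHASES[self.strategy]
        return second if second is not None else first

    def breakpoints(self) -> list[float]:
        """Times at which the forcing is discontinuous (phase boundaries)."""
        pts = [0.0, self.T]
        if self.is_combination:
            pts.insert(1, self.T_s)
        return pts


def phase_at(t: float, plan: ReleasePlan) -> Optional[int]:
    """Active released strain (0-based genotype position) at time ``t``.

    Returns ``None`` outside the release window; maintenance phases past
    ``T`` are handled by the scenario driver, not here.
    """
    if t < 0:
        raise PlanError(f"time must be nonnegative, got {t}")
    first, second = STRATEGY_PHASES[plan.strategy]
    if t >= plan.T:
        return None
    if second is not None and t >= plan.T_s:
        return second
    return first


def allocate_rates(
    strain: int, total_rate: float, female_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split a total daily release rate into per-genotype (R_M, R_F) vectors.

    FK-strain (KKaa) females are competent vectors, so their allocation is
    reassigned to males; the total released is unchanged.
    """
    R_M = np.zeros(N_GENOTYPES)
    R_F = np.zeros(N_GENOTYPES)
    phi = 0.0 if strain == IDX_FK else female_fraction
    R_F[strain] = phi * total_rate
    R_M[strain] = (1.0 - phi) * total_rate
    return R_M, R_F


def release_rates_at(
    t: float, plan: ReleasePlan, M_bar: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype adult release rates (R_M, R_F), individuals/day, at time t."""
    if M_bar <= 0:
        raise PlanError("M_bar must be positive")
    strain = phase_at(t, plan)
    if strain is None:
        return np.zeros(N_GENOTYPES), np.zeros(N_GENOTYPES)
    total = plan.r * M_bar / 7.0
    return allocate_rates(strain, total, plan.female_fraction)
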