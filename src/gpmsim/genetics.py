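"""Two-locus genotype bookkeeping, Mendelian inheritance, fitness and viability.

The simulator tracks two unlinked autosomal loci in *Aedes aegypti*: a
female-killing locus with transgenic allele ``K`` (wild-type ``k``) and an
antipathogen locus with transgenic allele ``A`` (wild-type ``a``).  The nine
two-locus genotypes are indexed 1..9 in a fixed order (``KKAA`` .. ``kkaa``);
every array in the package uses this order.

Genotype *i* carries ``k_copies`` copies of K and ``a_copies`` copies of A.
Offspring genotype probabilities follow independent Mendelian segregation at
each locus; relative fitness is additive within a locus and multiplicative
across loci; females carrying any K copy die before adulthood unless released
as adults under conditional repression of the lethal element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_GENOTYPES = 9

#: (k_copies, a_copies) for genotype indices 1..9, in the canonical row order.
GENOTYPE_COPIES: tuple[tuple[int, int], ...] = (
    (2, 2),  # 1 KKAA
    (1, 2),  # 2 KkAA
    (0, 2),  # 3 kkAA
    (2, 1),  # 4 KKAa
    (1, 1),  # 5 KkAa
    (0, 1),  # 6 kkAa
    (2, 0),  # 7 KKaa
    (1, 0),  # 8 Kkaa
    (0, 0),  # 9 kkaa
)

GENOTYPE_NAMES: tuple[str, ...] = (
    "KKAA", "KkAA", "kkAA", "KKAa", "KkAa", "kkAa", "KKaa", "Kkaa", "kkaa",
)

# Released strains (0-based array positions).
IDX_RR = 0   # KKAA, homozygous reduce-and-replace strain
IDX_AP = 2   # kkAA, homozygous antipathogen strain
IDX_FK = 6   # KKaa, homozygous female-killing strain
IDX_WT = 8   # kkaa, wild type (competent-vector class)


class InvalidGenotypeError(ValueError):
    """Raised when allele copy numbers fall outside {0, 1, 2}."""


@dataclass(frozen=True)
class Genotype:
    """One of the nine two-locus genotypes.

    Parameters
    ----------
    index : int
        1-based genotype index in the canonical order (1=KKAA .. 9=kkaa).
    """

    index: int

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_GENOTYPES:
            raise InvalidGenotypeError(f"genotype index must be 1..9, got {self.index}")

    @property
    def k_copies(self) -> int:
        return GENOTYPE_COPIES[self.index - 1][0]

    @property
    def a_copies(self) -> int:
        return GENOTYPE_COPIES[self.index - 1][1]

    @property
    def name(self) -> str:
        return GENOTYPE_NAMES[self.index - 1]

    @classmethod
    def from_copies(cls, k_copies: int, a_copies: int) -> "Genotype":
        try:
            pos = GENOTYPE_COPIES.index((k_copies, a_copies))
        except ValueError:
            raise InvalidGenotypeError(
                f"allele copies must each be in {{0,1,2}}, got ({k_copies}, {a_copies})"
            ) from None
        return cls(pos + 1)


@dataclass(frozen=True)
class FitnessSpec:
    """Homozygous fitness costs of the two transgenes.

    ``c_K`` (female-killing locus) and ``c_A`` (antipathogen locus) are
    dimensionless costs in [0, 1]; heterozygotes pay half the homozygous cost
    (additive within a locus) and costs multiply across loci.
    """

    c_K: float = 0.0
    c_A: float = 0.0

    def __post_init__(self) -> None:
        for label, c in (("c_K", self.c_K), ("c_A", self.c_A)):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {c}")


def gamete_distribution(copies: int) -> np.ndarray:
    """Probability of transmitting 0 or 1 copy of an allele carried ``copies`` times.

    Returns ``[P(not transmit), P(transmit)]``; transmission probability is
    ``copies / 2`` under Mendelian segregation.
    """
    if copies not in (0, 1, 2):
        raise InvalidGenotypeError(f"allele copy number must be 0, 1 or 2, got {copies}")
    p = copies / 2.0
    return np.array([1.0 - p, p])


def _locus_offspring_matrix() -> np.ndarray:
    """P(offspring copies | mother copies, father copies) at a single locus.

    Shape (3, 3, 3): offspring copy number is the sum of one maternal and one
    paternal gamete draw.
    """
    out = np.zeros((3, 3, 3))
    for m in range(3):
        gm = gamete_distribution(m)
        for n in range(3):
            gn = gamete_distribution(n)
            for cm in range(2):
                for cn in range(2):
                    out[m, n, cm + cn] += gm[cm] * gn[cn]
    return out


def build_inheritance_tensor() -> np.ndarray:
    """Offspring genotype distribution for every parental pair.

    Returns the 9x9x9 array ``p[m, n, i]`` = probability that a mating of
    mother genotype ``m`` and father genotype ``n`` (0-based positions in the
    canonical order) yields offspring genotype ``i``.  Loci segregate
    independently, so each entry is the product of per-locus terms.
    """
    locus = _locus_offspring_matrix()
    p = np.zeros((N_GENOTYPES, N_GENOTYPES, N_GENOTYPES))
    for m, (mk, ma) in enumerate(GENOTYPE_COPIES):
        for n, (nk, na) in enumerate(GENOTYPE_COPIES):
            for i, (ik, ia) in enumerate(GENOTYPE_COPIES):
                p[m, n, i] = locus[mk, nk, ik] * locus[ma, na, ia]
    return p


def fitness(g: Genotype, spec: FitnessSpec) -> float:
    """Relative fitness w_i = (1 - (k/2) c_K) (1 - (a/2) c_A)."""
    return (1.0 - 0.5 * g.k_copies * spec.c_K) * (1.0 - 0.5 * g.a_copies * spec.c_A)


def fitness_vector(spec: FitnessSpec) -> np.ndarray:
    """w_i for all nine genotypes in canonical order."""
    return np.array([fitness(Genotype(i), spec) for i in range(1, N_GENOTYPES + 1)])


def female_viability(g: Genotype) -> int:
    """Viability indicator gamma_i: 1 iff the genotype carries no K allele.

    Any K copy kills females before emergence (the lethal element is
    female-specific and dominant); adult K-carrying females can still be
    *released* because rearing represses the element.
    """
    return 1 if g.k_copies == 0 else 0


def viability_vector() -> np.ndarray:
    """gamma_i for all nine genotypes in canonical order."""
    return np.array(
        [female_viability(Genotype(i)) for i in range(1, N_GENOTYPES + 1)], dtype=float
    )
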