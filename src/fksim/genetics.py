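"""Female-killing (FK) transgene genetics.

An FK strain carries a dominant, female-specific lethal construct inserted
at 1–4 unlinked autosomal loci.  A genotype records the FK copy number
(0, 1 or 2) at each locus.  Any adult female with at least one copy at any
locus dies on the day she emerges from pupation; males are unaffected
carriers.  Loci segregate independently (insertions sit on separate linkage
groups), and an optional per-locus fitness cost ``c`` gives relative
fitnesses 1, (1−c)^0.5 and (1−c) for 0/1/2 copies, multiplied across loci.

Genotypes are plain tuples of per-locus copy numbers, with a compact string
form ("2/2/2" for a 3-locus homozygote) and a dense integer index (base-3
digits) used by the vectorized population engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "Genotype",
    "StrainSpec",
    "GeneticsConfig",
    "MAX_LOCI",
    "wild_type",
    "homozygous",
    "genotype_to_index",
    "index_to_genotype",
    "format_genotype",
    "parse_genotype",
    "cross",
    "offspring_index_probs",
    "sample_offspring_counts",
    "female_viable_at_emergence",
    "relative_fitness",
    "carries_fk",
]

Genotype = tuple[int, ...]

MAX_LOCI = 4


def _validate(genotype: Genotype) -> Genotype:
    g = tuple(int(c) for c in genotype)
    if not (1 <= len(g) <= MAX_LOCI):
        raise ValueError(f"genotype must have 1..{MAX_LOCI} loci, got {len(g)}")
    if any(c not in (0, 1, 2) for c in g):
        raise ValueError(f"per-locus copy numbers must be 0, 1 or 2: {g}")
    return g


@dataclass(frozen=True)
class StrainSpec:
    """A released FK strain: homozygous at ``n_loci`` unlinked loci."""

    n_loci: int = 1
    homozygous: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.n_loci <= MAX_LOCI):
            raise ValueError(f"n_loci must be 1..{MAX_LOCI}")
        if not self.homozygous:
            raise ValueError("released strains are homozygous at all loci")

    @property
    def genotype(self) -> Genotype:
        return homozygous(self.n_loci)


@dataclass(frozen=True)
class GeneticsConfig:
    """Fitness cost and mating competitiveness of the FK strain.

    ``fitness_cost`` is the per-locus cost ``c``; ``mating_competitiveness``
    multiplies an FK-carrier male's weight in the weight-proportional mate
    draw (1 = equal to wild type).  ``penetrance`` of female lethality is
    kept as an explicit knob but fixed at 1 (complete lethality) in every
    default scenario.
    """

    fitness_cost: float = 0.0
    mating_competitiveness: float = 1.0
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fitness_cost < 1.0):
            raise ValueError("fitness_cost must be in [0, 1)")
        if self.mating_competitiveness < 0:
            raise ValueError("mating_competitiveness must be >= 0")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError("penetrance must be in [0, 1]")


def wild_type(n_loci: int) -> Genotype:
    return (0,) * n_loci


def homozygous(n_loci: int) -> Genotype:
    return (2,) * n_loci


def genotype_to_index(genotype: Genotype) -> int:
    """Dense base-3 index; locus 0 is the least significant digit."""
    g = _validate(genotype)
    idx = 0
    for c in reversed(g):
        idx = idx * 3 + c
    return idx


def index_to_genotype(index: int, n_loci: int) -> Genotype:
    copies = []
    for _ in range(n_loci):
        copies.append(index % 3)
        index //= 3
    if index:
        raise ValueError("index out of range for n_loci")
    return tuple(copies)


def format_genotype(genotype: Genotype) -> str:
    return "/".join(str(c) for c in _validate(genotype))


def parse_genotype(text: str) -> Genotype:
    return _validate(tuple(int(p) for p in text.split("/")))


def carries_fk(genotype: Genotype) -> bool:
    return any(c > 0 for c in _validate(genotype))


# ---------------------------------------------------------------------------
# inheritance


def cross(maternal: Genotype, paternal: Genotype, rng: np.random.Generator) -> Genotype:
    """One offspring genotype under independent Mendelian segregation.

    At each locus the offspring receives one allele drawn uniformly from
    each parent's two alleles; a parent with ``c`` copies transmits the FK
    allele with probability ``c/2``.
    """
    m = _validate(maternal)
    p = _validate(paternal)
    if len(m) != len(p):
        raise ValueError(f"parental locus counts differ: {len(m)} vs {len(p)}")
    u = rng.random(size=(2, len(m)))
    child = tuple(
        int(u[0, i] < m[i] / 2.0) + int(u[1, i] < p[i] / 2.0) for i in range(len(m))
    )
    return child


@lru_cache(maxsize=None)
def _offspring_probs_cached(maternal: Genotype, paternal: Genotype) -> tuple[float, ...]:
    probs = np.array([1.0])
    for cm, cp in zip(maternal, paternal):
        pm, pp = cm / 2.0, cp / 2.0
        locus = np.array(
            [
                (1 - pm) * (1 - pp),
                pm * (1 - pp) + (1 - pm) * pp,
                pm * pp,
            ]
        )
        # base-3 digit order: earlier loci are less significant
        probs = (locus[:, None] * probs[None, :]).T.reshape(-1)
    return tuple(probs)


def offspring_index_probs(maternal: Genotype, paternal: Genotype) -> np.ndarray:
    """Offspring genotype distribution over dense indices 0..3^L−1."""
    m = _validate(maternal)
    p = _validate(paternal)
    if len(m) != len(p):
        raise ValueError(f"parental locus counts differ: {len(m)} vs {len(p)}")
    return np.array(_offspring_probs_cached(m, p))


def sample_offspring_counts(
    maternal: Genotype,
    paternal: Genotype,
    n_offspring,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial offspring genotype counts for one or more broods.

    ``n_offspring`` may be a scalar (returns a vector over genotype indices)
    or a vector of brood sizes (returns a matrix, one row per brood).
    """
    probs = offspring_index_probs(maternal, paternal)
    n = np.asarray(n_offspring)
    if n.ndim == 0:
        return rng.multinomial(int(n), probs)
    return rng.multinomial(n.astype(np.int64), probs)


# ---------------------------------------------------------------------------
# phenotype


def female_viable_at_emergence(genotype: Genotype, sex: str) -> bool:
    """Whether an emerging adult survives the FK lethality check.

    False iff the individual is female and carries >= 1 FK copy at any
    locus (lethality acts on the first day of adult life); males are always
    viable.
    """
    g = _validate(genotype)
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if sex == "male":
        return True
    return not carries_fk(g)


def relative_fitness(genotype: Genotype, c: float) -> float:
    """Multiplicative relative fitness: per locus 1, (1−c)^0.5 or (1−c)."""
    g = _validate(genotype)
    if not (0.0 <= c < 1.0):
        raise ValueError("fitness cost c must be in [0, 1)")
    return float(np.prod([(1.0 - c) ** (copies / 2.0) for copies in g]))


def fitness_by_index(n_loci: int, c: float) -> np.ndarray:
    """Relative fitness for every genotype index 0..3^L−1 (vector lookup)."""
    return np.array(
        [relative_fitness(index_to_genotype(i, n_loci), c) for i in range(3**n_loci)]
    )


def fk_carrier_by_index(n_loci: int) -> np.ndarray:
    """Boolean lookup: does genotype index i carry at least one FK copy."""
    return np.array(
        [carries_fk(index_to_genotype(i, n_loci)) for i in range(3**n_loci)]
    )
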