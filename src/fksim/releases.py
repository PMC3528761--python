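"""Intervention engine: FK releases, pre-release insecticide, compliance.

Releases are weekly.  Spatial patterns: ``homogeneous`` (every house; adult
releases only), ``uniform_sites`` (a near-square sublattice covering a
fraction of houses, default 10%) and ``random_sites`` (the same number of
houses drawn uniformly without replacement).  Release sites stay fixed for
the whole program, except for permanent compliance-driven dropout.

Adult releases add homozygous FK males at each active site; a
deterministically rounded fraction of each cohort ("early dispersers") is
instead placed at houses drawn uniformly at random anywhere on the grid
except the release site itself.  Egg releases add, each week per active
site, a fresh shielded container with effectively unlimited food, seeded
half-and-half with male and female homozygous FK eggs; only males emerge
(FK females die at emergence) and the container is withdrawn once the
cohort is exhausted.

A pre-release insecticide round adds a large daily excess mortality to
adults for a fixed window ending the day before releases start; each house
independently misses treatment with a small daily probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetics
from .environment import Environment
from .genetics import StrainSpec
from .params import ModelParams
from .population import FEMALE, MALE, SimulationState

__all__ = [
    "ReleasePlan",
    "InsecticidePlan",
    "SiteSet",
    "select_sites",
    "release_adults",
    "release_eggs",
    "apply_insecticide",
    "update_compliance",
    "release_ratio",
]

_PATTERNS = ("homogeneous", "uniform_sites", "random_sites")


@dataclass
class ReleasePlan:
    """One weekly release program."""

    stage: str = "adults"  # "adults" | "eggs"
    pattern: str = "homogeneous"
    site_fraction: float = 0.10
    number_per_site_per_week: int = 0
    strain: StrainSpec = field(default_factory=StrainSpec)
    early_disperser_fraction: float = 0.0
    start_day: int = 365
    duration_weeks: int = 156
    compliance_decline_per_year: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in ("adults", "eggs"):
            raise ValueError(f"stage must be 'adults' or 'eggs', got {self.stage!r}")
        if self.pattern not in _PATTERNS:
            raise ValueError(f"pattern must be one of {_PATTERNS}")
        if self.pattern == "homogeneous" and self.stage != "adults":
            raise ValueError("homogeneous releases are defined for adults only")
        for name in ("site_fraction", "early_disperser_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.compliance_decline_per_year < 1.0):
            raise ValueError("compliance_decline_per_year must be in [0, 1)")
        if self.number_per_site_per_week < 0:
            raise ValueError("number_per_site_per_week must be >= 0")

    def is_release_day(self, day: int) -> bool:
        if day < self.start_day:
            return False
        weeks = (day - self.start_day) // 7
        return (day - self.start_day) % 7 == 0 and weeks < self.duration_weeks

    def week_index(self, day: int) -> int:
        return (day - self.start_day) // 7


@dataclass
class InsecticidePlan:
    """Pre-release adulticide window (adults only; immatures unaffected)."""

    duration_days: int = 14
    extra_daily_mortality: float = 0.90
    miss_probability: float = 0.10
    end_day: int = 364  # last treated day; releases start the next day

    def __post_init__(self) -> None:
        if not (0.0 <= self.extra_daily_mortality <= 1.0):
            raise ValueError("extra_daily_mortality must be in [0, 1]")
        if not (0.0 <= self.miss_probability <= 1.0):
            raise ValueError("miss_probability must be in [0, 1]")

    def active(self, day: int) -> bool:
        return self.end_day - self.duration_days + 1 <= day <= self.end_day


@dataclass
class SiteSet:
    """Fixed release-site membership with per-site participation flags."""

    houses: np.ndarray  # flat house indices
    active: np.ndarray  # participation flags (compliance dropout is permanent)

    def __post_init__(self) -> None:
        self.houses = np.asarray(self.houses, dtype=np.int64)
        self.active = np.asarray(self.active, dtype=bool)
        if len(self.houses) != len(self.active):
            raise ValueError("houses/active length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.houses)

    @property
    def active_houses(self) -> np.ndarray:
        return self.houses[self.active]

    def to_frame(self, grid) -> pd.DataFrame:
        rows, cols = np.divmod(self.houses, grid.cols)
        return pd.DataFrame({"row": rows, "col": cols, "active": self.active})


def select_sites(
    env: Environment,
    pattern: str = "random_sites",
    site_fraction: float = 0.10,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> SiteSet:
    """Choose release sites.

    ``homogeneous``: every house.  Point-source patterns place sites at a
    number set by the near-square sublattice geometry: with target spacing
    ``sqrt(1/fraction)`` houses, a grid of ``round(rows/spacing) ×
    round(cols/spacing)`` sites covers ≈ ``fraction`` of houses (242 on a
    68×36 grid at 10%).  ``uniform_sites`` uses that sublattice itself
    (deterministic given the grid); ``random_sites`` draws the same number
    of distinct houses uniformly without replacement.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"pattern must be one of {_PATTERNS}")
    grid = env.grid
    n_houses = grid.n_houses
    if pattern == "homogeneous":
        houses = np.arange(n_houses)
        return SiteSet(houses=houses, active=np.ones(n_houses, dtype=bool))
    if not (0.0 < site_fraction <= 1.0):
        raise ValueError("site_fraction must be in (0, 1]")
    if int(round(site_fraction * n_houses)) == 0:
        raise ValueError(f"site_fraction {site_fraction} yields 0 sites")
    spacing = math.sqrt(1.0 / site_fraction)
    nr = min(grid.rows, max(1, round(grid.rows / spacing)))
    nc = min(grid.cols, max(1, round(grid.cols / spacing)))
    n_sites = nr * nc
    if pattern == "random_sites":
        if isinstance(seed, np.random.Generator):
            rng = seed
        else:
            ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
            rng = np.random.Generator(np.random.PCG64(ss))
        houses = rng.choice(n_houses, size=n_sites, replace=False)
        return SiteSet(houses=np.sort(houses), active=np.ones(n_sites, dtype=bool))
    r_pos = np.floor((np.arange(nr) + 0.5) * grid.rows / nr).astype(int)
    c_pos = np.floor((np.arange(nc) + 0.5) * grid.cols / nc).astype(int)
    houses = np.array([r * grid.cols + c for r in r_pos for c in c_pos], dtype=np.int64)
    return SiteSet(houses=houses, active=np.ones(n_sites, dtype=bool))


def release_adults(
    state: SimulationState,
    plan: ReleasePlan,
    sites: SiteSet,
    params: ModelParams | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """Add one weekly cohort of homozygous FK male adults per active site.

    ``round(early_disperser_fraction × number)`` of each site's cohort is
    placed at houses chosen uniformly at random among all houses except the
    release site; the rest stay at the site.  No-op on non-release days.
    Released adults get the default wild-type adult weight and follow
    normal daily dynamics thereafter.
    """
    if not plan.is_release_day(state.day):
        return state
    rng = rng or state.rng
    n = plan.number_per_site_per_week
    if n <= 0:
        return state
    geno = genetics.genotype_to_index(plan.strain.genotype)
    if plan.strain.n_loci != state.n_loci:
        raise ValueError(
            f"strain has {plan.strain.n_loci} loci but state tracks {state.n_loci}"
        )
    weight = (
        params.released_adult_weight_mg if params is not None
        else _default_adult_weight(state)
    )
    n_away = int(round(plan.early_disperser_fraction * n))
    n_home = n - n_away
    n_houses = state.env.grid.n_houses
    active = sites.active_houses
    if len(active) == 0:
        return state
    placements = []
    if n_home > 0:
        placements.append(np.repeat(active, n_home))
    if n_away > 0:
        # early dispersers: uniform over all houses except the release site
        dest = rng.integers(0, n_houses - 1, size=(len(active), n_away))
        dest = np.where(dest >= active[:, None], dest + 1, dest)
        placements.append(dest.ravel())
    houses = np.concatenate(placements)
    state.add_adults(len(houses), house=houses, sex=MALE, genotype=geno,
                     weight=weight, released=True)
    return state


def _default_adult_weight(state: SimulationState) -> float:
    from .params import default_params

    return default_params().released_adult_weight_mg


def release_eggs(
    state: SimulationState,
    plan: ReleasePlan,
    sites: SiteSet,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """Add one weekly shielded egg-release container per active site.

    The container has an optimal nutrient supply (larval growth never
    food-limited), is invisible to ovipositing wild females, and is seeded
    with ``number_per_site_per_week`` homozygous FK eggs split as evenly as
    possible between the sexes (odd totals give the extra egg to males).
    It is withdrawn automatically once all its occupants died or emerged.
    """
    if not plan.is_release_day(state.day):
        return state
    n = plan.number_per_site_per_week
    if n <= 0:
        return state
    if plan.strain.n_loci != state.n_loci:
        raise ValueError(
            f"strain has {plan.strain.n_loci} loci but state tracks {state.n_loci}"
        )
    geno = genetics.genotype_to_index(plan.strain.genotype)
    n_male = (n + 1) // 2
    n_female = n - n_male
    new_ci = []
    for house in sites.active_houses:
        new_ci.append(
            state.add_container(
                house=int(house),
                capacity=params.release_capacity_l,
                water=params.release_water_l,
                food_input=params.release_food_input_mg,
                food=params.release_initial_food_mg,
                shielded=True,
                removable=True,
            )
        )
    ci = np.asarray(new_ci, dtype=np.int64)
    state.cohorts.append(
        container=np.repeat(ci, 2),
        stage=np.int8(0),  # EGG
        sex=np.tile(np.array([MALE, FEMALE], dtype=np.int8), len(ci)),
        genotype=np.int16(geno),
        count=np.tile(np.array([n_male, n_female], dtype=np.int64), len(ci)),
        dev=0.0,
        weight=0.0,
        age=np.int16(0),
    )
    return state


def apply_insecticide(state: SimulationState, plan: InsecticidePlan):
    """Insecticide directive for the current day, or None outside the window.

    Returns the ``(miss_probability, extra_daily_mortality)`` pair consumed
    by :func:`fksim.population.step_day`; each house is then independently
    treated that day with probability ``1 − miss_probability`` and its
    adults suffer the extra mortality after nominal survival.
    """
    if plan is None or not plan.active(state.day):
        return None
    return (plan.miss_probability, plan.extra_daily_mortality)


def update_compliance(
    sites: SiteSet,
    plan: ReleasePlan,
    week: int,
    rng: np.random.Generator,
) -> SiteSet:
    """Weekly permanent site dropout from declining community participation.

    Each still-active site drops out this week with probability ``q`` where
    ``(1−q)^52 = 1 − annual_decline``, so the expected active fraction after
    52 weeks equals ``1 − annual_decline``.  Dropped sites never reactivate.
    """
    decline = plan.compliance_decline_per_year
    if decline <= 0.0 or week < 0:
        return sites
    q = 1.0 - (1.0 - decline) ** (1.0 / 52.0)
    drop = rng.random(sites.n_sites) < q
    sites.active &= ~drop
    return sites


def release_ratio(
    number_per_site_per_week: float, n_sites: int, wild_male_count: float
) -> float:
    """Initial release ratio: weekly released FK males per resident wild male."""
    if wild_male_count <= 0:
        raise ValueError("wild male count must be positive")
    return number_per_site_per_week * n_sites / wild_male_count
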