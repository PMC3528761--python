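"""Daily-step stochastic population dynamics.

Immature mosquitoes (eggs, larvae, pupae) are tracked as cohorts within
individual containers; adults are tracked individually within houses.  One
call to :func:`step_day` advances the state by one day, applying, in this
fixed order:

1. adult survival (plus any insecticide excess mortality) and aging,
2. nominal immature survival,
3. container food dynamics and larval weight update (density-dependent
   competition, starvation mortality),
4. development accumulation and stage transitions (hatch → larva,
   pupate → pupa, emerge → adult, with the FK female-lethality check at
   emergence),
5. mating (weight-proportional mate choice within the house, strict
   female monogamy),
6. oviposition (egg batches placed in non-shielded containers of the
   female's house, destination probability proportional to capacity),
7. adult dispersal (probability ``dispersal_probability`` per day to a
   uniformly chosen existing orthogonal neighbor).

Total individuals change only through death, emergence and oviposition.

Larval competition is a deliberately simple saturating-intake scheme in the
spirit of the Gilpin–McClelland food/weight formulation: each larva demands
food in proportion to W^(2/3); a container's realized intake fraction is
``u = F/(F + D)`` for food stock F and total demand D, so per-capita intake
falls as cohorts grow; weight and larval development advance in proportion
to intake above a maintenance fraction, and larvae driven below a
starvation weight suffer extra daily mortality.  Under abundant food
(``u → 1``) larvae complete development in the configured minimum time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genetics
from .environment import Environment
from .genetics import GeneticsConfig
from .params import ModelParams

__all__ = [
    "EGG",
    "LARVA",
    "PUPA",
    "MALE",
    "FEMALE",
    "ContainerArrays",
    "CohortArrays",
    "AdultArrays",
    "SimulationState",
    "initialize_state",
    "step_day",
    "aggregate_state",
    "update_larval_food",
    "develop_and_transition",
    "mate_females",
    "oviposit",
    "disperse_adults",
    "simulate_male_lifespans",
    "dispersal_reach_probability",
]

EGG, LARVA, PUPA = 0, 1, 2
MALE, FEMALE = 0, 1

_INT = np.int64
_FLOAT = np.float64


class _SoA:
    """Minimal struct-of-arrays container with append/compress."""

    _fields: dict[str, np.dtype] = {}

    def __init__(self, **arrays) -> None:
        n = None
        for name, dtype in self._fields.items():
            arr = np.asarray(arrays.get(name, np.empty(0, dtype=dtype)), dtype=dtype)
            setattr(self, name, arr)
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValueError(f"field {name} length mismatch")

    def __len__(self) -> int:
        return len(getattr(self, next(iter(self._fields))))

    def compress(self, mask: np.ndarray) -> None:
        for name in self._fields:
            setattr(self, name, getattr(self, name)[mask])

    def append(self, **arrays) -> None:
        n_new = None
        for v in arrays.values():
            n_new = len(np.atleast_1d(v))
            break
        if not n_new:
            return
        for name, dtype in self._fields.items():
            if name not in arrays:
                raise ValueError(f"missing field {name}")
            new = np.broadcast_to(np.asarray(arrays[name], dtype=dtype), (n_new,))
            setattr(self, name, np.concatenate([getattr(self, name), new]))


class ContainerArrays(_SoA):
    """Runtime container table (parallel to the environment's container list)."""

    _fields = {
        "house": _INT,
        "capacity": _FLOAT,
        "water": _FLOAT,
        "food_input": _FLOAT,
        "food": _FLOAT,
        "shielded": np.bool_,
        "removable": np.bool_,
        "alive": np.bool_,
    }

    @classmethod
    def from_environment(cls, env: Environment) -> "ContainerArrays":
        cs = env.containers
        return cls(
            house=[c.house for c in cs],
            capacity=[c.capacity for c in cs],
            water=[c.water_level for c in cs],
            food_input=[c.food_input for c in cs],
            food=[c.food_amount for c in cs],
            shielded=[c.shielded for c in cs],
            removable=[c.removable for c in cs],
            alive=[True] * len(cs),
        )


class CohortArrays(_SoA):
    """Immature cohorts: one row per (container, stage, sex, genotype, birth-day)."""

    _fields = {
        "container": _INT,
        "stage": np.int8,
        "sex": np.int8,
        "genotype": np.int16,
        "count": _INT,
        "dev": _FLOAT,
        "weight": _FLOAT,
        "age": np.int16,
    }

    def total(self) -> int:
        return int(self.count.sum())


class AdultArrays(_SoA):
    """Individual adults: one row per living adult."""

    _fields = {
        "id": _INT,
        "house": _INT,
        "sex": np.int8,
        "genotype": np.int16,
        "age": np.int16,
        "weight": _FLOAT,
        "mated": np.bool_,
        "mate_genotype": np.int16,
        "gono": _FLOAT,
        "released": np.bool_,
    }


@dataclass
class SimulationState:
    """All simulated state at one day, plus the seeded random stream."""

    day: int
    env: Environment
    containers: ContainerArrays
    cohorts: CohortArrays
    adults: AdultArrays
    rng: np.random.Generator
    n_loci: int
    neighbor_table: np.ndarray = field(repr=False, default=None)
    neighbor_counts: np.ndarray = field(repr=False, default=None)
    next_adult_id: int = 0
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.neighbor_table is None:
            self.neighbor_table, self.neighbor_counts = self.env.grid.neighbor_table()
        self.stats.setdefault("emerged_males", 0)
        self.stats.setdefault("emerged_females", 0)
        self.stats.setdefault("fk_female_deaths", 0)
        self.stats.setdefault("emerged_release_males", 0)

    # -- summaries --------------------------------------------------------
    def n_adult_females(self) -> int:
        return int(np.count_nonzero(self.adults.sex == FEMALE))

    def n_adult_males(self, resident_only: bool = False) -> int:
        m = self.adults.sex == MALE
        if resident_only:
            m &= ~self.adults.released
        return int(np.count_nonzero(m))

    def n_resident_adults(self) -> int:
        return int(np.count_nonzero(~self.adults.released))

    def n_resident_immatures(self) -> int:
        if len(self.cohorts) == 0:
            return 0
        resident = ~self.containers.removable[self.cohorts.container]
        return int(self.cohorts.count[resident].sum())

    def add_adults(
        self,
        n: int,
        house,
        sex: int,
        genotype: int,
        weight: float,
        released: bool = False,
        gono: float = 0.0,
    ) -> None:
        if n <= 0:
            return
        ids = np.arange(self.next_adult_id, self.next_adult_id + n, dtype=_INT)
        self.next_adult_id += n
        self.adults.append(
            id=ids,
            house=house,
            sex=np.int8(sex),
            genotype=np.int16(genotype),
            age=np.int16(0),
            weight=weight,
            mated=False,
            mate_genotype=np.int16(-1),
            gono=gono,
            released=released,
        )

    def add_container(
        self,
        house: int,
        capacity: float,
        water: float,
        food_input: float,
        food: float,
        shielded: bool = False,
        removable: bool = False,
    ) -> int:
        """Append one container; returns its runtime index."""
        self.containers.append(
            house=house,
            capacity=capacity,
            water=water,
            food_input=food_input,
            food=food,
            shielded=shielded,
            removable=removable,
            alive=True,
        )
        return len(self.containers) - 1


def initialize_state(
    env: Environment,
    params: ModelParams,
    n_loci: int = 1,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    init_eggs_per_container: int = 20,
) -> SimulationState:
    """Fresh state seeded with wild-type eggs in every container.

    Each container starts with ``init_eggs_per_container`` eggs, split as
    evenly as possible between the sexes (sex is assigned at laying).
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rng = np.random.Generator(np.random.PCG64(ss))
    containers = ContainerArrays.from_environment(env)
    cohorts = CohortArrays()
    n_c = len(containers)
    if n_c and init_eggs_per_container > 0:
        half = init_eggs_per_container // 2
        rest = init_eggs_per_container - half
        idx = np.arange(n_c)
        cohorts.append(
            container=np.repeat(idx, 2),
            stage=np.int8(EGG),
            sex=np.tile(np.array([MALE, FEMALE], dtype=np.int8), n_c),
            genotype=np.int16(0),
            count=np.tile(np.array([rest, half], dtype=_INT), n_c),
            dev=0.0,
            weight=0.0,
            age=np.int16(0),
        )
        mask = cohorts.count > 0
        cohorts.compress(mask)
    return SimulationState(
        day=0,
        env=env,
        containers=containers,
        cohorts=cohorts,
        adults=AdultArrays(),
        rng=rng,
        n_loci=n_loci,
    )


# ---------------------------------------------------------------------------
# grouped weighted sampling (mate choice, oviposition-site choice)


def _grouped_weighted_choice(
    group_of_item: np.ndarray,
    weights: np.ndarray,
    query_groups: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each query, draw one item from its group w.p. proportional to weight.

    Queries whose group has no items (or zero total weight) get -1.
    Returns indices into the item arrays.
    """
    result = np.full(len(query_groups), -1, dtype=_INT)
    if len(group_of_item) == 0 or len(query_groups) == 0:
        return result
    order = np.argsort(group_of_item, kind="stable")
    g_sorted = group_of_item[order]
    w_sorted = weights[order].astype(_FLOAT)
    cumw = np.cumsum(w_sorted)
    uniq, starts = np.unique(g_sorted, return_index=True)
    ends = np.append(starts[1:], len(g_sorted))
    pos = np.searchsorted(uniq, query_groups)
    valid = (pos < len(uniq)) & (uniq[np.minimum(pos, len(uniq) - 1)] == query_groups)
    if not np.any(valid):
        return result
    pos = pos[valid]
    lo = starts[pos]
    hi = ends[pos]
    base = np.where(lo > 0, cumw[lo - 1], 0.0)
    tot = cumw[hi - 1] - base
    ok = tot > 0
    u = rng.random(len(pos)) * tot + base
    picked = np.searchsorted(cumw, u, side="left")
    picked = np.clip(picked, lo, hi - 1)
    out = np.where(ok, order[picked], -1)
    idx_valid = np.flatnonzero(valid)
    result[idx_valid] = out
    return result


# ---------------------------------------------------------------------------
# daily sub-steps


def _adult_survival(
    state: SimulationState, params: ModelParams, insecticide=None
) -> None:
    a = state.adults
    n = len(a)
    if n == 0:
        return
    p = np.where(a.sex == FEMALE, params.adult_female_survival, params.adult_male_survival)
    if params.fk_male_survival != params.adult_male_survival:
        fk_males = (a.sex == MALE) & a.released
        p = np.where(fk_males, params.fk_male_survival, p)
    alive = state.rng.random(n) < p
    if insecticide is not None:
        miss_prob, extra_mortality = insecticide
        treated = state.rng.random(state.env.grid.n_houses) >= miss_prob
        hit = treated[a.house]
        extra_dead = hit & (state.rng.random(n) < extra_mortality)
        alive &= ~extra_dead
    a.compress(alive)
    a.age += 1


def _immature_survival(state: SimulationState, params: ModelParams) -> None:
    c = state.cohorts
    if len(c) == 0:
        return
    s = np.array([params.egg_survival, params.larva_survival, params.pupa_survival])
    surv_p = s[c.stage]
    c.count = state.rng.binomial(c.count, surv_p)
    c.age += 1
    c.compress(c.count > 0)


def update_larval_food(state: SimulationState, params: ModelParams) -> np.ndarray:
    """Daily food bookkeeping and larval weight update for every container.

    Returns the per-cohort intake fraction ``u`` (1 for non-larval cohorts),
    which also scales larval development in :func:`develop_and_transition`.
    """
    c = state.cohorts
    cont = state.containers
    n_cont = len(cont)
    u_cohort = np.ones(len(c))
    # food arrives every day regardless of occupancy
    food = cont.food + np.where(cont.alive, cont.food_input, 0.0)
    larv = c.stage == LARVA
    if np.any(larv):
        idx = np.flatnonzero(larv)
        demand_i = (
            c.count[idx] * params.feeding_coeff * np.maximum(c.weight[idx], 1e-6) ** (2.0 / 3.0)
        )
        D = np.bincount(c.container[idx], weights=demand_i, minlength=n_cont)
        with np.errstate(divide="ignore", invalid="ignore"):
            u_cont = np.where(D > 0, food / (food + D), 1.0)
        consumed = u_cont * D
        food = food - consumed
        u = u_cont[c.container[idx]]
        u_cohort[idx] = u
        # weight changes in proportion to intake above maintenance
        t_factor = params.thermal_factor(state.env.weather[state.day])
        gain_max = (params.pupation_weight_mg - params.hatch_weight_mg) / params.larva_days
        um = params.maintenance_fraction
        growth = gain_max * (u - um) / (1.0 - um) * t_factor
        c.weight[idx] = np.maximum(c.weight[idx] + growth, 0.01)
        # starvation: intake below maintenance, or weight driven below the
        # starvation threshold, incurs extra daily mortality
        deficit = np.clip((um - u) / um, 0.0, 1.0) if um > 0 else np.zeros_like(u)
        underweight = c.weight[idx] < params.starvation_weight_mg
        p_starve = params.starvation_mortality * np.maximum(deficit, underweight)
        starving = p_starve > 0
        if np.any(starving):
            sidx = idx[starving]
            c.count[sidx] = state.rng.binomial(
                c.count[sidx], 1.0 - p_starve[starving]
            )
        # stalled larvae cannot persist indefinitely
        too_old = c.age[idx] > params.max_larva_days
        if np.any(too_old):
            c.count[idx[too_old]] = 0
    cont.food = np.maximum(food, 0.0) * (1.0 - params.food_decay)
    if np.any(c.count == 0):
        keep = c.count > 0
        u_cohort = u_cohort[keep]
        c.compress(keep)
    return u_cohort


def _transition_probability(dev: np.ndarray, ramp: float) -> np.ndarray:
    """Smooth per-day transition probability once development nears 1.

    Individuals transition over a window of width 2*ramp centred on
    completion, which spreads a same-day cohort's emergence over ~2–3 days.
    """
    return np.clip((dev - (1.0 - ramp)) / (2.0 * ramp), 0.0, 1.0)


def develop_and_transition(
    state: SimulationState,
    params: ModelParams,
    genetics_cfg: GeneticsConfig,
    larval_dev_factor: np.ndarray | None = None,
) -> None:
    """Advance development and perform hatch / pupation / emergence.

    Eggs require standing water in their container to hatch; larvae must
    reach the pupation weight; emerging FK-carrying females are removed
    (female lethality at emergence, with configurable penetrance).  An
    optional per-locus fitness cost is charged as a viability multiplier
    ``f^(1/3)`` at each of the three transitions, so it compounds to ``f``
    across the full immature development.
    """
    c = state.cohorts
    if len(c) == 0:
        return
    T = state.env.weather[state.day]
    rng = state.rng

    rate = np.empty(len(c))
    rate[c.stage == EGG] = params.dev_rate(params.egg_days, T)
    rate[c.stage == PUPA] = params.dev_rate(params.pupa_days, T)
    lmask = c.stage == LARVA
    lrate = params.dev_rate(params.larva_days, T)
    if larval_dev_factor is not None:
        um = params.maintenance_fraction
        g = np.clip((larval_dev_factor[lmask] - um) / (1.0 - um), 0.0, 1.0)
        # development is slowed less than growth under food shortage, so
        # crowded larvae mature late but small (stunted adults)
        rate[lmask] = lrate * np.sqrt(g)
    else:
        rate[lmask] = lrate
    c.dev += rate

    p_tr = _transition_probability(c.dev, params.ramp)
    # eggs hatch in installments (a short egg bank) and only into wet containers
    egg_mask = c.stage == EGG
    p_tr[egg_mask] = np.minimum(p_tr[egg_mask], params.egg_hatch_daily_max)
    has_water = state.containers.water[c.container] > 0
    p_tr[egg_mask & ~has_water] = 0.0
    p_tr[(c.stage == LARVA) & (c.weight < params.min_pupation_weight_mg)] = 0.0

    n_tr = rng.binomial(c.count, p_tr)
    moving = n_tr > 0
    if not np.any(moving):
        return
    c.count -= n_tr

    # fitness cost: viability multiplier per transition
    cost = genetics_cfg.fitness_cost
    if cost > 0:
        fit = genetics.fitness_by_index(state.n_loci, cost) ** (1.0 / 3.0)
        n_tr = rng.binomial(n_tr, fit[c.genotype])
        moving = n_tr > 0

    idx = np.flatnonzero(moving)
    stages = c.stage[idx]

    # hatch: egg -> larva
    h = idx[stages == EGG]
    if len(h):
        c.append(
            container=c.container[h],
            stage=np.int8(LARVA),
            sex=c.sex[h],
            genotype=c.genotype[h],
            count=n_tr[h],
            dev=0.0,
            weight=params.hatch_weight_mg,
            age=np.int16(0),
        )

    # pupate: larva -> pupa (carries its larval weight)
    pnew = idx[stages == LARVA]
    if len(pnew):
        c.append(
            container=c.container[pnew],
            stage=np.int8(PUPA),
            sex=c.sex[pnew],
            genotype=c.genotype[pnew],
            count=n_tr[pnew],
            dev=0.0,
            weight=c.weight[pnew],
            age=np.int16(0),
        )

    # emerge: pupa -> adult, FK lethality check on females
    e = idx[stages == PUPA]
    if len(e):
        carrier = genetics.fk_carrier_by_index(state.n_loci)
        n_e = n_tr[e]
        is_female = c.sex[e] == FEMALE
        lethal = is_female & carrier[c.genotype[e]]
        survivors = n_e.copy()
        if np.any(lethal):
            pen = genetics_cfg.penetrance
            killed = rng.binomial(n_e[lethal], pen)
            survivors[lethal] = n_e[lethal] - killed
            state.stats["fk_female_deaths"] += int(killed.sum())
        from_release = state.containers.removable[c.container[e]]
        state.stats["emerged_males"] += int(n_e[~is_female].sum())
        state.stats["emerged_females"] += int(survivors[is_female].sum())
        state.stats["emerged_release_males"] += int(
            n_e[~is_female & from_release].sum()
        )
        keep = survivors > 0
        if np.any(keep):
            reps = survivors[keep]
            ek = e[keep]
            sexes = np.repeat(c.sex[ek], reps)
            # first gonotrophic cycle is longer: blood-feeding and egg
            # maturation precede the first oviposition
            gono0 = np.where(
                sexes == FEMALE,
                -params.first_gono_extra_days / params.gonotrophic_days,
                0.0,
            )
            state.add_adults(
                int(reps.sum()),
                house=np.repeat(state.containers.house[c.container[ek]], reps),
                sex=sexes,
                genotype=np.repeat(c.genotype[ek], reps),
                weight=np.repeat(c.weight[ek] * params.adult_weight_fraction, reps),
                released=np.repeat(from_release[keep], reps),
                gono=gono0,
            )

    c.compress(c.count > 0)
    _merge_fresh_cohorts(c)
    _coarsen_cohorts(c)
    _retire_exhausted_release_containers(state)


def _merge_fresh_cohorts(c: CohortArrays) -> None:
    """Merge same-day cohorts with identical (container, stage, sex, genotype).

    Freshly created cohorts (dev == 0) from the same transition day are
    biologically exchangeable; merging keeps the cohort table compact.
    Weights are combined as count-weighted means.
    """
    fresh = (c.dev == 0.0) & (c.age == 0)
    idx = np.flatnonzero(fresh)
    if len(idx) < 2:
        return
    key = (
        c.container[idx] * 24
        + c.stage[idx].astype(_INT) * 8
        + c.sex[idx].astype(_INT) * 4
    ) * 128 + c.genotype[idx].astype(_INT)
    uniq, first_pos, inv = np.unique(key, return_index=True, return_inverse=True)
    if len(uniq) == len(idx):
        return
    tot = np.bincount(inv, weights=c.count[idx].astype(float))
    wsum = np.bincount(inv, weights=c.count[idx] * c.weight[idx])
    firsts = idx[first_pos]
    c.count[firsts] = tot.astype(_INT)
    c.weight[firsts] = wsum / np.maximum(tot, 1.0)
    keep = np.zeros(len(idx), dtype=bool)
    keep[first_pos] = True
    mask = np.ones(len(c), dtype=bool)
    mask[idx[~keep]] = False
    c.compress(mask)


def _coarsen_cohorts(c: CohortArrays, n_bins: int = 8) -> None:
    """Pool cohorts at matching development stage to bound the cohort table.

    Cohorts sharing (container, stage, sex, genotype) whose development
    fractions fall in the same 1/``n_bins`` bin are pooled with
    count-weighted mean development, weight and age.  This caps the cohort
    table at a fixed per-container resolution; the binning is finer than
    the transition ramp, so the induced smearing of transition days is
    below the model's own stochastic spread.
    """
    if len(c) < 2:
        return
    devbin = np.minimum((c.dev * n_bins).astype(_INT), 2 * n_bins - 1)
    key = (
        ((c.container * 4 + c.stage) * 2 + c.sex).astype(_INT) * 128
        + c.genotype
    ) * (2 * n_bins) + devbin
    uniq, first, inv = np.unique(key, return_index=True, return_inverse=True)
    if len(uniq) == len(c):
        return
    w = c.count.astype(float)
    tot = np.bincount(inv, weights=w)
    c.count[first] = tot.astype(_INT)
    c.dev[first] = np.bincount(inv, weights=w * c.dev) / tot
    c.weight[first] = np.bincount(inv, weights=w * c.weight) / tot
    c.age[first] = np.round(np.bincount(inv, weights=w * c.age) / tot).astype(np.int16)
    mask = np.zeros(len(c), dtype=bool)
    mask[first] = True
    c.compress(mask)


def _retire_exhausted_release_containers(state: SimulationState) -> None:
    cont = state.containers
    removable = cont.removable & cont.alive
    if not np.any(removable):
        return
    occupied = np.zeros(len(cont), dtype=bool)
    if len(state.cohorts):
        occupied[np.unique(state.cohorts.container)] = True
    cont.alive &= ~(removable & ~occupied)


def mate_females(
    state: SimulationState,
    genetics_cfg: GeneticsConfig,
    params: ModelParams | None = None,
) -> None:
    """Assign mates to unmated females, weight-proportionally within houses.

    Each receptive unmated female (females become receptive
    ``female_mating_age_days`` after emergence) in a house with at least
    one male receives a mate with probability proportional to male weight
    (times the FK mating competitiveness for carrier males); the mate's
    genotype is stored for all her future ovipositions.  Females in
    male-free houses stay unmated and retry the next day.  Mated females
    are never re-mated (monogamy).
    """
    a = state.adults
    receptive = (a.sex == FEMALE) & ~a.mated
    if params is not None and params.female_mating_age_days > 0:
        receptive &= a.age >= params.female_mating_age_days
    females = np.flatnonzero(receptive)
    if len(females) == 0:
        return
    males = np.flatnonzero(a.sex == MALE)
    if len(males) == 0:
        return
    weights = a.weight[males].copy()
    if genetics_cfg.mating_competitiveness != 1.0:
        carrier = genetics.fk_carrier_by_index(state.n_loci)
        weights[carrier[a.genotype[males]]] *= genetics_cfg.mating_competitiveness
    chosen = _grouped_weighted_choice(
        a.house[males], weights, a.house[females], state.rng
    )
    got = chosen >= 0
    f = females[got]
    m = males[chosen[got]]
    a.mated[f] = True
    a.mate_genotype[f] = a.genotype[m]


def oviposit(state: SimulationState, params: ModelParams) -> None:
    """Advance gonotrophic cycles and lay egg batches.

    A mated female's gonotrophic progress accumulates at the
    temperature-scaled cycle rate; on reaching 1 she deposits a batch of
    ``eggs_per_batch`` eggs into one non-shielded, water-holding container
    of her current house (chosen with probability proportional to
    capacity), after which her progress resets.  If no eligible container
    exists the batch is deferred to the next day.  Offspring genotypes are
    multinomial draws from the Mendelian cross of the female with her
    stored mate; sex is assigned 50:50 at laying.
    """
    a = state.adults
    mated = np.flatnonzero(a.mated)
    if len(mated) == 0:
        return
    T = state.env.weather[state.day]
    a.gono[mated] += params.dev_rate(params.gonotrophic_days, T)
    ready = mated[a.gono[mated] >= 1.0]
    if len(ready) == 0:
        return
    cont = state.containers
    eligible = np.flatnonzero(cont.alive & ~cont.shielded & (cont.water > 0))
    if len(eligible) == 0:
        return
    target = _grouped_weighted_choice(
        cont.house[eligible], cont.capacity[eligible], a.house[ready], state.rng
    )
    laying = target >= 0
    if not np.any(laying):
        return
    ready = ready[laying]
    target_c = eligible[target[laying]]
    a.gono[ready] = 0.0

    L = state.n_loci
    n_geno = 3**L
    batch = params.eggs_per_batch
    pair_key = a.genotype[ready].astype(_INT) * n_geno + a.mate_genotype[ready].astype(_INT)
    acc: dict[tuple[int, int, int], int] = {}
    egg_matrix = np.zeros((len(cont), 2 * n_geno), dtype=_INT)
    for key in np.unique(pair_key):
        sel = pair_key == key
        mg = genetics.index_to_genotype(int(key) // n_geno, L)
        fg = genetics.index_to_genotype(int(key) % n_geno, L)
        pg = genetics.offspring_index_probs(mg, fg)
        # class index = genotype*2 + sex, each sex with probability 1/2
        probs = np.repeat(pg, 2) * 0.5
        counts = state.rng.multinomial(batch, probs, size=int(sel.sum()))
        np.add.at(egg_matrix, target_c[sel], counts)
    rows, cols = np.nonzero(egg_matrix)
    if len(rows) == 0:
        return
    state.cohorts.append(
        container=rows.astype(_INT),
        stage=np.int8(EGG),
        sex=(cols % 2).astype(np.int8),
        genotype=(cols // 2).astype(np.int16),
        count=egg_matrix[rows, cols],
        dev=0.0,
        weight=0.0,
        age=np.int16(0),
    )


def disperse_adults(state: SimulationState, params: ModelParams) -> None:
    """Move each adult, w.p. ``dispersal_probability``, to a random neighbor.

    The destination is uniform among the house's existing orthogonal
    neighbors (edge and corner houses have 3 and 2); the rule is identical
    for both sexes and for released males.  One exception: a gravid female
    whose batch is overdue (no eligible container in her current house)
    moves with certainty — oviposition-site seeking.
    """
    a = state.adults
    n = len(a)
    if n == 0 or params.dispersal_probability <= 0:
        return
    move = state.rng.random(n) < params.dispersal_probability
    seeking = (a.sex == FEMALE) & a.mated & (a.gono >= 1.0)
    move |= seeking
    if not np.any(move):
        return
    movers = np.flatnonzero(move)
    h = a.house[movers]
    k = (state.rng.random(len(movers)) * state.neighbor_counts[h]).astype(_INT)
    a.house[movers] = state.neighbor_table[h, k]


def step_day(
    state: SimulationState,
    params: ModelParams,
    genetics_cfg: GeneticsConfig | None = None,
    insecticide=None,
) -> SimulationState:
    """Advance the simulation by one day (mutates and returns ``state``).

    ``insecticide``, when given, is a ``(miss_probability, extra_mortality)``
    pair applied to adults this day: each house is independently treated
    with probability ``1 − miss_probability`` and adults in treated houses
    suffer the extra death probability after nominal survival.
    """
    if state.day >= len(state.env.weather):
        raise IndexError(
            f"weather series (length {len(state.env.weather)}) does not cover day {state.day}"
        )
    if genetics_cfg is None:
        genetics_cfg = GeneticsConfig()
    _adult_survival(state, params, insecticide)
    _immature_survival(state, params)
    u = update_larval_food(state, params)
    develop_and_transition(state, params, genetics_cfg, larval_dev_factor=u)
    mate_females(state, genetics_cfg, params)
    oviposit(state, params)
    disperse_adults(state, params)
    state.day += 1
    return state


def aggregate_state(state: SimulationState, per_house: bool = False):
    """Aggregated counts of the current state as a tidy DataFrame.

    One row per (stage, sex, genotype-class) — plus house when
    ``per_house`` — with stages ``egg``/``larva``/``pupa``/``adult`` and
    genotypes in compact string form ("2/2/2" for a 3-locus homozygote).
    """
    import pandas as pd

    from .genetics import format_genotype, index_to_genotype

    stage_names = {EGG: "egg", LARVA: "larva", PUPA: "pupa"}
    sex_names = {MALE: "male", FEMALE: "female"}
    rows = []
    c = state.cohorts
    for i in range(len(c)):
        rows.append(
            (
                int(state.containers.house[c.container[i]]),
                stage_names[int(c.stage[i])],
                sex_names[int(c.sex[i])],
                format_genotype(index_to_genotype(int(c.genotype[i]), state.n_loci)),
                int(c.count[i]),
            )
        )
    a = state.adults
    for i in range(len(a)):
        rows.append(
            (
                int(a.house[i]),
                "adult",
                sex_names[int(a.sex[i])],
                format_genotype(index_to_genotype(int(a.genotype[i]), state.n_loci)),
                1,
            )
        )
    df = pd.DataFrame(rows, columns=["house", "stage", "sex", "genotype", "count"])
    keys = ["house", "stage", "sex", "genotype"] if per_house else ["stage", "sex", "genotype"]
    out = df.groupby(keys, as_index=False)["count"].sum()
    out.insert(0, "day", state.day)
    return out


# ---------------------------------------------------------------------------
# emergent single-behaviour simulations (lifespan, dispersal reach)


def simulate_male_lifespans(
    n: int,
    params: ModelParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    chunk: int = 250_000,
) -> np.ndarray:
    """Simulated adult male lifespans (days) under nominal daily survival.

    Each male survives each day independently with probability
    ``adult_male_survival``; the lifespan counts the day of death, so the
    closed form for its mean is ``1/(1−s)`` days.
    """
    from .params import default_params

    params = params or default_params()
    s = params.adult_male_survival
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    out = []
    remaining = n
    while remaining > 0:
        m = min(chunk, remaining)
        out.append(rng.geometric(1.0 - s, size=m))
        remaining -= m
    return np.concatenate(out)


def dispersal_reach_probability(
    n_walkers: int,
    max_distance: int = 5,
    params: ModelParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    horizon_days: int = 120,
    chunk: int = 200_000,
) -> float:
    """Probability an adult male ever exceeds ``max_distance`` grid steps.

    Monte-Carlo on an unbounded grid: each day a walker survives with the
    nominal male survival and moves with the daily dispersal probability one
    step in a uniformly random orthogonal direction.  Distance is the
    Manhattan (grid-step) distance from the origin; the walk is truncated at
    ``horizon_days`` (survival to that age is already ~1e-12 at defaults).
    """
    from .params import default_params

    params = params or default_params()
    s = params.adult_male_survival
    pd = params.dispersal_probability
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    exceeded_total = 0
    done = 0
    dx = np.array([1, -1, 0, 0])
    dy = np.array([0, 0, 1, -1])
    while done < n_walkers:
        m = min(chunk, n_walkers - done)
        x = np.zeros(m, dtype=np.int32)
        y = np.zeros(m, dtype=np.int32)
        alive = np.ones(m, dtype=bool)
        exceeded = np.zeros(m, dtype=bool)
        for _ in range(horizon_days):
            alive &= rng.random(m) < s
            active = alive & ~exceeded
            if not np.any(active):
                break
            idx = np.flatnonzero(active)
            move = rng.random(len(idx)) < pd
            mi = idx[move]
            d = rng.integers(0, 4, size=len(mi))
            x[mi] += dx[d]
            y[mi] += dy[d]
            exceeded[mi] |= (np.abs(x[mi]) + np.abs(y[mi])) > max_distance
        exceeded_total += int(exceeded.sum())
        done += m
    return exceeded_total / n_walkers
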