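"""Replicated scenario execution and outcome metrics.

A scenario couples one synthetic city with a release program and runs it
for ``n_replicates`` independent stochastic replicates: each replicate is
initialized with 20 wild-type eggs in every container, burned in for a year
so the resident population reaches quasi-equilibrium, optionally treated
with a two-week pre-release insecticide round, and then subjected to weekly
FK releases for the control horizon (3 years by default).

Outcomes per replicate: whether the *resident* population was eliminated
(no immatures outside shielded release containers and no adults other than
currently-alive released FK males — externally replenished individuals do
not count against elimination), the elimination day, the time to 90%
reduction of the adult-female density relative to a 21-day pre-release
baseline, and the daily female/male time series.  Scenario-level summaries
report elimination proportions with binomial standard errors and averaged
times to 90% reduction (replicates that never reach 90% are excluded and
counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .environment import (
    Environment,
    GridSpec,
    HeterogeneitySettings,
    apply_heterogeneity,
    build_environment,
)
from .genetics import GeneticsConfig
from .params import ModelParams, default_params
from .population import SimulationState, initialize_state, step_day
from .releases import (
    InsecticidePlan,
    ReleasePlan,
    SiteSet,
    apply_insecticide,
    release_adults,
    release_eggs,
    select_sites,
    update_compliance,
)

__all__ = [
    "ScenarioConfig",
    "ReplicateResult",
    "build_scenario_environment",
    "run_scenario",
    "run_replicate",
    "detect_elimination",
    "time_to_90_reduction",
    "summarize_times",
    "suppression_efficacy",
    "proportion_with_se",
    "threshold_sweep",
    "summarize_scenario",
]


@dataclass
class ScenarioConfig:
    """Everything needed to run one replicated scenario."""

    rows: int = 20
    cols: int = 20
    containers_per_house: object = None  # default: Poisson with the params mean
    phi: int = 2  # 2 leaves the container distribution unchanged
    params: ModelParams = field(default_factory=default_params)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)
    release: ReleasePlan | None = None
    insecticide: InsecticidePlan | None = None
    n_replicates: int = 30
    burn_in: int = 365
    horizon_days: int = 1095  # 3 years of control
    init_eggs_per_container: int = 20
    master_seed: int = 0
    env_seed: int = 1234  # city layout; fixed across sweep levels

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.release is not None and self.release.start_day < self.burn_in:
            raise ValueError("releases must not start before the end of burn-in")

    @property
    def total_days(self) -> int:
        return self.burn_in + self.horizon_days

    @property
    def release_start(self) -> int:
        return self.release.start_day if self.release else self.burn_in


def scenario_from_yaml(path) -> ScenarioConfig:
    """Load a scenario from a YAML document.

    Top-level keys mirror :class:`ScenarioConfig`; ``params`` holds
    overrides of the default :class:`~fksim.params.ModelParams` fields,
    ``release`` a :class:`~fksim.releases.ReleasePlan` mapping (with
    ``strain_loci`` for the strain), and ``insecticide`` an
    :class:`~fksim.releases.InsecticidePlan` mapping.
    """
    import yaml

    from .genetics import StrainSpec

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    params = default_params()
    if doc.get("params"):
        params = params.replace(**doc["params"])
    release = None
    if doc.get("release"):
        rel = dict(doc["release"])
        loci = rel.pop("strain_loci", 1)
        release = ReleasePlan(strain=StrainSpec(n_loci=int(loci)), **rel)
    insecticide = InsecticidePlan(**doc["insecticide"]) if doc.get("insecticide") else None
    fields = {
        k: doc[k]
        for k in (
            "rows", "cols", "containers_per_house", "phi", "n_replicates",
            "burn_in", "horizon_days", "init_eggs_per_container",
            "master_seed", "env_seed",
        )
        if k in doc
    }
    return ScenarioConfig(params=params, release=release, insecticide=insecticide, **fields)


def build_scenario_environment(config: ScenarioConfig) -> Environment:
    """The scenario's city, deterministic given ``env_seed``.

    One city layout is shared by all replicates (and, in sweeps, by all
    release levels); only the population dynamics differ among replicates.
    """
    p = config.params
    cph = config.containers_per_house
    if cph is None:
        cph = ("poisson", p.containers_per_house_poisson)
    env = build_environment(
        GridSpec(config.rows, config.cols),
        containers_per_house=cph,
        container_profile={
            "capacity": p.container_capacity_l,
            "water_level": p.container_water_l,
            "food_input": p.container_food_input_mg,
            "food_amount": p.container_initial_food_mg,
        },
        weather_params={
            "n_days": config.total_days + 7,
            "mean": p.weather_mean_c,
            "amplitude": p.weather_amplitude_c,
            "noise_sd": p.weather_noise_sd_c,
        },
        seed=np.random.SeedSequence(config.env_seed),
    )
    if config.phi > 2:
        env = apply_heterogeneity(
            env,
            HeterogeneitySettings(
                phi=config.phi, seed=np.random.SeedSequence(config.env_seed + 1)
            ),
        )
    return env


@dataclass
class ReplicateResult:
    """Outcome record of one replicate."""

    eliminated: bool
    elimination_day: int | None  # days since release start
    time_to_90: int | None  # days since release start
    female_series: np.ndarray  # daily adult females, whole run
    male_series: np.ndarray  # daily resident adult males

    def __post_init__(self) -> None:
        self.female_series = np.asarray(self.female_series, dtype=np.int64)
        self.male_series = np.asarray(self.male_series, dtype=np.int64)


def detect_elimination(state: SimulationState) -> bool:
    """True iff the resident population is gone.

    Resident means: any immature cohort outside shielded/removable release
    containers, plus any adult that was not externally released.  Currently
    alive released FK males and unemerged release-container cohorts are
    externally replenished and do not count.
    """
    return state.n_resident_immatures() == 0 and state.n_resident_adults() == 0


def run_replicate(
    config: ScenarioConfig,
    env: Environment,
    seed: np.random.SeedSequence,
    stop_at_elimination: bool = True,
) -> ReplicateResult:
    """One full stochastic replicate on a prebuilt environment."""
    state_ss, sites_ss = seed.spawn(2)
    release = config.release
    n_loci = release.strain.n_loci if release else 1
    state = initialize_state(
        env,
        config.params,
        n_loci=n_loci,
        seed=state_ss,
        init_eggs_per_container=config.init_eggs_per_container,
    )
    sites: SiteSet | None = None
    if release is not None:
        sites = select_sites(
            env, release.pattern, release.site_fraction, seed=sites_ss
        )
    total_days = config.total_days
    release_start = config.release_start
    females = np.zeros(total_days, dtype=np.int64)
    males = np.zeros(total_days, dtype=np.int64)
    eliminated = False
    elimination_day: int | None = None

    for day in range(total_days):
        if release is not None and release.is_release_day(day):
            week = release.week_index(day)
            if release.compliance_decline_per_year > 0 and week > 0:
                update_compliance(sites, release, week, state.rng)
            if release.stage == "adults":
                release_adults(state, release, sites, config.params)
            else:
                release_eggs(state, release, sites, config.params)
        directive = (
            apply_insecticide(state, config.insecticide)
            if config.insecticide is not None
            else None
        )
        step_day(state, config.params, config.genetics, insecticide=directive)
        females[day] = state.n_adult_females()
        males[day] = state.n_adult_males(resident_only=True)
        if not eliminated and day >= release_start and detect_elimination(state):
            eliminated = True
            elimination_day = day - release_start
            if stop_at_elimination:
                # resident extinction is absorbing: only released males remain
                break

    t90 = time_to_90_reduction(females, release_start)
    return ReplicateResult(
        eliminated=eliminated,
        elimination_day=elimination_day,
        time_to_90=t90,
        female_series=females,
        male_series=males,
    )


def run_scenario(
    config: ScenarioConfig,
    env: Environment | None = None,
    stop_on_failure: bool = False,
) -> list[ReplicateResult]:
    """Run all replicates of a scenario (independent seeded substreams).

    ``stop_on_failure`` aborts remaining replicates as soon as one fails to
    eliminate — useful inside all-replicates-eliminate threshold scans,
    where a single failure already settles the level.
    """
    if env is None:
        env = build_scenario_environment(config)
    streams = np.random.SeedSequence(config.master_seed).spawn(config.n_replicates)
    results: list[ReplicateResult] = []
    for ss in streams:
        res = run_replicate(config, env, ss)
        results.append(res)
        if stop_on_failure and not res.eliminated:
            break
    return results


# ---------------------------------------------------------------------------
# metrics


def time_to_90_reduction(
    female_series: np.ndarray, release_start: int
) -> int | None:
    """First day (since release start) the female count drops to <=10% of baseline.

    Baseline is the mean adult-female count over the 21 days before the
    release start.  Returns None if the series never reaches the 90%
    reduction within its length.
    """
    series = np.asarray(female_series, dtype=float)
    if release_start < 21:
        raise ValueError("series must cover at least 21 days before release start")
    baseline = series[release_start - 21 : release_start].mean()
    if baseline <= 0:
        raise ValueError("pre-release baseline density is zero")
    below = np.flatnonzero(series[release_start:] <= 0.10 * baseline)
    if len(below) == 0:
        return None
    return int(below[0])


def summarize_times(values: Sequence[int | None]) -> tuple[float | None, float | None, int]:
    """Mean and SD over non-None times, plus the exclusion count."""
    kept = np.array([v for v in values if v is not None], dtype=float)
    n_excluded = len(values) - len(kept)
    if len(kept) == 0:
        return None, None, n_excluded
    sd = float(kept.std(ddof=1)) if len(kept) > 1 else 0.0
    return float(kept.mean()), sd, n_excluded


def suppression_efficacy(female_series: np.ndarray, release_start: int) -> float:
    """Percent reduction of adult-female density.

    Reference window: mean over the 21 days before the release start;
    suppressed window: mean over days 200–400 after it.
    """
    series = np.asarray(female_series, dtype=float)
    if release_start < 21:
        raise ValueError("series must cover at least 21 days before release start")
    if len(series) < release_start + 401:
        raise ValueError("series must cover release_start + 400 days")
    ref = series[release_start - 21 : release_start].mean()
    if ref <= 0:
        raise ValueError("reference density is zero")
    post = series[release_start + 200 : release_start + 401].mean()
    return 100.0 * (1.0 - post / ref)


def proportion_with_se(outcomes: Sequence[bool], n: int | None = None) -> tuple[float, float]:
    """Binomial point estimate and standard error sqrt(p(1−p)/n)."""
    flags = np.asarray(outcomes, dtype=bool)
    n = len(flags) if n is None else n
    if n < 1:
        raise ValueError("n must be >= 1")
    p = flags.sum() / n
    return float(p), float(np.sqrt(p * (1.0 - p) / n))


def summarize_scenario(results: Sequence[ReplicateResult]) -> dict:
    """Scenario-level summary: elimination proportion ± SE, times to 90%."""
    p, se = proportion_with_se([r.eliminated for r in results])
    mean_t90, sd_t90, excluded = summarize_times([r.time_to_90 for r in results])
    elim_days = [r.elimination_day for r in results if r.elimination_day is not None]
    return {
        "n_replicates": len(results),
        "elimination_proportion": p,
        "elimination_se": se,
        "mean_time_to_90": mean_t90,
        "sd_time_to_90": sd_t90,
        "n_excluded_time_to_90": excluded,
        "mean_elimination_day": float(np.mean(elim_days)) if elim_days else None,
    }


# ---------------------------------------------------------------------------
# threshold sweeps


def _criterion_fn(criterion) -> Callable[[list[ReplicateResult]], bool]:
    if callable(criterion):
        return criterion
    if criterion == "all_eliminated":
        return lambda rs: all(r.eliminated for r in rs)
    if isinstance(criterion, tuple) and len(criterion) == 2:
        kind, x = criterion
        if kind == "proportion_ge":
            return lambda rs: (sum(r.eliminated for r in rs) / len(rs)) >= x
        if kind == "time_to_90_le":
            def fn(rs: list[ReplicateResult]) -> bool:
                mean, _, excluded = summarize_times([r.time_to_90 for r in rs])
                return excluded == 0 and mean is not None and mean <= x
            return fn
    raise ValueError(f"unknown criterion {criterion!r}")


def threshold_sweep(
    config: ScenarioConfig,
    levels: Sequence[int],
    criterion="all_eliminated",
    early_stop: bool = False,
    scan_until_success: bool = False,
    runner: Callable[[ScenarioConfig], list[ReplicateResult]] | None = None,
) -> tuple[int | None, pd.DataFrame]:
    """Find the smallest weekly release level meeting a success criterion.

    Each level is run as an independent scenario (fresh replicate
    substreams, same city).  ``early_stop`` (valid for the
    ``all_eliminated`` criterion) aborts a level's remaining replicates at
    the first failed replicate; ``scan_until_success`` stops the ascending
    scan at the first satisfying level (the minimal level is unchanged;
    higher levels are simply not run).  Returns
    ``(minimal_level_or_None, table)`` with the per-level outcome table.
    """
    if list(levels) != sorted(levels):
        raise ValueError("levels must be ascending")
    if config.release is None:
        raise ValueError("config must carry a release plan to sweep over")
    crit = _criterion_fn(criterion)
    use_stop = early_stop and criterion == "all_eliminated"
    rows = []
    satisfied: int | None = None
    base_ss = np.random.SeedSequence(config.master_seed)
    level_seeds = base_ss.spawn(len(levels))
    env = build_scenario_environment(config)
    for level, lss in zip(levels, level_seeds):
        cfg = replace(
            config,
            release=replace(config.release, number_per_site_per_week=int(level)),
        )
        if runner is not None:
            results = runner(cfg)
        else:
            streams = lss.spawn(cfg.n_replicates)
            results = []
            for ss in streams:
                res = run_replicate(cfg, env, ss)
                results.append(res)
                if use_stop and not res.eliminated:
                    break
        ok = crit(results) and (not use_stop or len(results) == config.n_replicates)
        summary = summarize_scenario(results)
        summary["level"] = level
        summary["criterion_met"] = ok
        rows.append(summary)
        if ok and satisfied is None:
            satisfied = int(level)
            if scan_until_success:
                break
    table = pd.DataFrame(rows).set_index("level")
    return satisfied, table
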