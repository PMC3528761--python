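"""Daily population dynamics: survival, competition, mating, dispersal."""

import numpy as np
import pytest
from scipy import stats

from fksim.environment import GridSpec, build_environment
from fksim.genetics import GeneticsConfig
from fksim.params import default_params
from fksim.population import (
    EGG,
    FEMALE,
    LARVA,
    MALE,
    PUPA,
    develop_and_transition,
    disperse_adults,
    dispersal_reach_probability,
    initialize_state,
    mate_females,
    simulate_male_lifespans,
    step_day,
    update_larval_food,
)

from conftest import make_env


def rng_for(seed):
    return np.random.Generator(np.random.PCG64(seed))


def fresh_state(env=None, params=None, n_loci=1, seed=1, init_eggs=0):
    p = params or default_params()
    env = env or make_env(params=p)
    return initialize_state(env, p, n_loci=n_loci, seed=seed,
                            init_eggs_per_container=init_eggs)


def add_egg_cohort(state, container=0, count=100, sex=MALE, genotype=0, dev=0.0):
    state.cohorts.append(
        container=np.array([container]),
        stage=np.int8(EGG),
        sex=np.int8(sex),
        genotype=np.int16(genotype),
        count=np.array([count], dtype=np.int64),
        dev=float(dev),
        weight=0.0,
        age=np.int16(0),
    )


class TestStepDay:
    def test_empty_state_just_advances_day(self, params):
        st = fresh_state(params=params)
        day = st.day
        step_day(st, params)
        assert st.day == day + 1
        assert len(st.adults) == 0 and len(st.cohorts) == 0

    def test_conservation_with_certain_survival(self, params):
        p = params.replace(
            egg_survival=1.0, larva_survival=1.0, pupa_survival=1.0,
            adult_female_survival=1.0, adult_male_survival=1.0,
            fk_male_survival=1.0, dispersal_probability=0.0,
        )
        st = fresh_state(params=p)
        add_egg_cohort(st, count=500, dev=0.0)
        st.add_adults(50, house=0, sex=MALE, genotype=0, weight=1.7)
        step_day(st, p)
        assert st.cohorts.total() == 500
        assert len(st.adults) == 50

    def test_adult_survival_binomial(self, params):
        st = fresh_state(params=params)
        st.add_adults(1000, house=0, sex=MALE, genotype=0, weight=1.7)
        step_day(st, params)
        survivors = len(st.adults)
        s = params.adult_male_survival
        assert abs(survivors - 1000 * s) < 3 * np.sqrt(1000 * s * (1 - s))

    def test_missing_weather_day_raises(self, params):
        env = make_env(n_days=5, params=params)
        st = fresh_state(env=env, params=params)
        for _ in range(5):
            step_day(st, params)
        with pytest.raises(IndexError):
            step_day(st, params)


class TestDevelopment:
    def test_no_hatching_without_water(self, params):
        p = params.replace(egg_survival=1.0)
        st = fresh_state(params=p)
        st.containers.water[:] = 0.0
        add_egg_cohort(st, count=200, dev=2.0)  # far past maturity
        for _ in range(5):
            step_day(st, p)
        c = st.cohorts
        assert c.count[c.stage == EGG].sum() == 200
        assert c.count[c.stage == LARVA].sum() == 0

    def test_abundant_food_reaches_pupation_near_minimum_time(self, params):
        # release-container nutrient level: growth never food-limited
        st = fresh_state(params=params)
        st.containers.food_input[:] = params.release_food_input_mg
        st.containers.food[:] = params.release_initial_food_mg
        st.cohorts.append(
            container=np.array([0]), stage=np.int8(LARVA), sex=np.int8(MALE),
            genotype=np.int16(0), count=np.array([1000], dtype=np.int64),
            dev=0.0, weight=params.hatch_weight_mg, age=np.int16(0),
        )
        p = params.replace(larva_survival=1.0, pupa_survival=1.0)
        days_to_half = None
        total0 = 1000
        for d in range(1, 30):
            step_day(st, p)
            c = st.cohorts
            pupated = total0 - c.count[c.stage == LARVA].sum()
            if days_to_half is None and pupated >= total0 / 2:
                days_to_half = d
        # thermal factor at 26 C is ~0.94, ramp is symmetric around completion
        assert days_to_half is not None
        assert abs(days_to_half - params.larva_days / 0.92) <= 2

    def test_fk_heterozygous_female_pupae_yield_no_adult_females(self, params):
        st = fresh_state(params=params, n_loci=1)
        st.cohorts.append(
            container=np.array([0]), stage=np.int8(PUPA), sex=np.int8(FEMALE),
            genotype=np.int16(1), count=np.array([1000], dtype=np.int64),
            dev=np.array([1.5]), weight=2.0, age=np.int16(0),
        )
        p = params.replace(pupa_survival=1.0)
        for _ in range(5):
            step_day(st, p)
        assert st.n_adult_females() == 0
        assert st.stats["fk_female_deaths"] == 1000

    def test_wild_female_pupae_do_emerge(self, params):
        st = fresh_state(params=params)
        st.cohorts.append(
            container=np.array([0]), stage=np.int8(PUPA), sex=np.int8(FEMALE),
            genotype=np.int16(0), count=np.array([1000], dtype=np.int64),
            dev=np.array([1.5]), weight=2.0, age=np.int16(0),
        )
        p = params.replace(pupa_survival=1.0, adult_female_survival=1.0)
        step_day(st, p)
        assert st.n_adult_females() == 1000


class TestLarvalFood:
    def test_food_grows_by_input_without_larvae(self, params):
        st = fresh_state(params=params)
        st.containers.food[:] = 10.0
        fi = st.containers.food_input.copy()
        update_larval_food(st, params)
        expected = (10.0 + fi) * (1.0 - params.food_decay)
        assert np.allclose(st.containers.food, expected)

    def test_doubling_larvae_lowers_per_capita_gain(self, params):
        gains = []
        for count in (50, 100):
            st = fresh_state(params=params)
            st.containers.food[:] = 5.0
            st.cohorts.append(
                container=np.array([0]), stage=np.int8(LARVA), sex=np.int8(MALE),
                genotype=np.int16(0), count=np.array([count], dtype=np.int64),
                dev=0.2, weight=0.5, age=np.int16(2),
            )
            w0 = st.cohorts.weight[0]
            p = params.replace(larva_survival=1.0, starvation_mortality=0.0)
            update_larval_food(st, p)
            gains.append(st.cohorts.weight[0] - w0)
        assert gains[1] < gains[0]

    def test_negative_food_input_rejected_at_construction(self):
        from fksim.environment import ContainerSpec

        with pytest.raises(ValueError):
            ContainerSpec(0, 0, capacity=5.0, water_level=5.0, food_input=-0.5)


class TestMating:
    def test_weight_proportional_selection(self, params):
        # two males of weight 2 and 4 mg -> probabilities 1/3 and 2/3
        st = fresh_state(params=params)
        st.add_adults(1, house=0, sex=MALE, genotype=0, weight=2.0)
        st.add_adults(1, house=0, sex=MALE, genotype=1, weight=4.0)
        n = 100_000
        st.add_adults(n, house=0, sex=FEMALE, genotype=0, weight=1.5)
        mate_females(st, GeneticsConfig())
        females = st.adults.sex == FEMALE
        assert np.all(st.adults.mated[females])
        frac_heavy = (st.adults.mate_genotype[females] == 1).mean()
        assert abs(frac_heavy - 2 / 3) < 3 * np.sqrt((2 / 9) / n)

    def test_no_males_leaves_female_unmated_until_males_appear(self, params):
        st = fresh_state(params=params)
        st.add_adults(1, house=4, sex=FEMALE, genotype=0, weight=1.5)
        mate_females(st, GeneticsConfig())
        assert not st.adults.mated[0]
        st.add_adults(1, house=4, sex=MALE, genotype=0, weight=1.7)
        mate_females(st, GeneticsConfig())
        assert st.adults.mated[st.adults.sex == FEMALE].all()

    def test_monogamy_mate_never_changes(self, params):
        st = fresh_state(params=params)
        st.add_adults(1, house=0, sex=MALE, genotype=1, weight=4.0)
        st.add_adults(1, house=0, sex=FEMALE, genotype=0, weight=1.5)
        mate_females(st, GeneticsConfig())
        fem = st.adults.sex == FEMALE
        assert st.adults.mate_genotype[fem][0] == 1
        # flood the house with wild males; the stored mate must not change
        st.add_adults(10, house=0, sex=MALE, genotype=0, weight=10.0)
        mate_females(st, GeneticsConfig())
        assert st.adults.mate_genotype[st.adults.sex == FEMALE][0] == 1

    def test_mating_competitiveness_multiplier(self, params):
        st = fresh_state(params=params)
        st.add_adults(1, house=0, sex=MALE, genotype=0, weight=2.0)
        st.add_adults(1, house=0, sex=MALE, genotype=2, weight=2.0)  # FK homozygote
        n = 50_000
        st.add_adults(n, house=0, sex=FEMALE, genotype=0, weight=1.5)
        mate_females(st, GeneticsConfig(mating_competitiveness=3.0))
        females = st.adults.sex == FEMALE
        frac_fk = (st.adults.mate_genotype[females] == 2).mean()
        assert abs(frac_fk - 0.75) < 3 * np.sqrt(0.1875 / n)


class TestOviposition:
    def _mated_female(self, st, house=0, mate_genotype=0):
        st.add_adults(1, house=house, sex=FEMALE, genotype=0, weight=1.5)
        idx = len(st.adults) - 1
        st.adults.mated[idx] = True
        st.adults.mate_genotype[idx] = mate_genotype
        st.adults.gono[idx] = 1.5
        return idx

    def test_shielded_container_never_chosen(self, params):
        env = make_env(rows=1, cols=1, containers=1, params=params)
        st = fresh_state(env=env, params=params)
        shielded_ci = st.add_container(house=0, capacity=1000.0, water=900.0,
                                       food_input=10.0, food=10.0, shielded=True)
        p = params.replace(adult_female_survival=1.0)
        for _ in range(30):
            self._mated_female(st)
            step_day(st, p)
        c = st.cohorts
        assert c.count[c.container == shielded_ci].sum() == 0
        assert c.total() > 0

    def test_wild_cross_gives_wild_eggs_and_even_sex_ratio(self, params):
        st = fresh_state(params=params)
        p = params.replace(adult_female_survival=1.0, egg_survival=1.0)
        n_females = 2000  # ~ 110k eggs
        for _ in range(n_females):
            self._mated_female(st)
        from fksim.population import oviposit

        oviposit(st, p)
        c = st.cohorts
        assert np.all(c.genotype == 0)
        total = c.count.sum()
        males = c.count[c.sex == MALE].sum()
        assert total == n_females * p.eggs_per_batch
        assert abs(males / total - 0.5) < 3 * np.sqrt(0.25 / total)

    def test_no_container_defers_batch(self, params):
        env = make_env(containers=0, params=params)
        st = fresh_state(env=env, params=params)
        idx = self._mated_female(st)
        from fksim.population import oviposit

        oviposit(st, params)
        assert len(st.cohorts) == 0
        assert st.adults.gono[idx] > 1.0  # batch retained for the next day


class TestDispersal:
    def test_moved_fraction_matches_daily_probability(self, params):
        env = make_env(rows=30, cols=30, containers=0, params=params)
        st = fresh_state(env=env, params=params)
        n = 100_000
        center = env.grid.house_index(15, 15)
        st.add_adults(n, house=center, sex=MALE, genotype=0, weight=1.7)
        disperse_adults(st, params)
        moved = (st.adults.house != center).mean()
        assert abs(moved - 0.30) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_zero_probability_freezes_everyone(self, params):
        st = fresh_state(params=params)
        st.add_adults(500, house=4, sex=FEMALE, genotype=0, weight=1.5)
        disperse_adults(st, params.replace(dispersal_probability=0.0))
        assert np.all(st.adults.house == 4)

    def test_corner_destination_uniform_over_two_neighbors(self, params):
        env = make_env(rows=5, cols=5, containers=0, params=params)
        st = fresh_state(env=env, params=params)
        n = 10_000
        st.add_adults(n, house=0, sex=MALE, genotype=0, weight=1.7)
        disperse_adults(st, params.replace(dispersal_probability=1.0))
        dest, counts = np.unique(st.adults.house, return_counts=True)
        assert set(dest) == {env.grid.house_index(0, 1), env.grid.house_index(1, 0)}
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.001


class TestAggregateState:
    def test_counts_and_genotype_strings(self, params):
        from fksim.population import aggregate_state

        st = fresh_state(params=params, n_loci=3)
        add_egg_cohort(st, count=40, sex=MALE, genotype=0)
        st.add_adults(3, house=1, sex=FEMALE, genotype=0, weight=1.5)
        st.add_adults(2, house=2, sex=MALE, genotype=26, weight=1.0)  # 2/2/2
        df = aggregate_state(st)
        assert set(df.columns) == {"day", "stage", "sex", "genotype", "count"}
        by_key = df.set_index(["stage", "sex", "genotype"])["count"]
        assert by_key[("egg", "male", "0/0/0")] == 40
        assert by_key[("adult", "female", "0/0/0")] == 3
        assert by_key[("adult", "male", "2/2/2")] == 2
        per_house = aggregate_state(st, per_house=True)
        assert per_house["count"].sum() == df["count"].sum()


class TestEmergentBehaviour:
    def test_male_lifespan_matches_geometric_closed_form(self, params):
        n = 100_000
        spans = simulate_male_lifespans(n, params, seed=7)
        s = params.adult_male_survival
        expected = 1.0 / (1.0 - s)
        sd = np.sqrt(s) / (1.0 - s)
        assert abs(spans.mean() - expected) < 3 * sd / np.sqrt(n)

    def test_dispersal_reach_beyond_5_houses_is_rare(self, params):
        p = dispersal_reach_probability(200_000, max_distance=5, params=params, seed=3)
        assert p < 0.01

    def test_persistence_without_releases(self, params):
        """Default calibration sustains the resident population for 2 years."""
        env = make_env(rows=8, cols=8, containers=("poisson", 1.5), noise_sd=0.5,
                       amplitude=1.0, n_days=760, params=params)
        for seed in (1, 2):
            st = initialize_state(env, params, seed=seed, init_eggs_per_container=20)
            males = []
            for _ in range(730):
                step_day(st, params)
                males.append(st.n_adult_males())
            males = np.array(males)
            assert males[365:].min() > 0  # no extinction
            # stationarity: second-year halves have comparable means
            h1, h2 = males[365:548].mean(), males[548:].mean()
            assert 0.5 < h2 / h1 < 2.0

    def test_determinism_bitwise_identical(self, params):
        env = make_env(rows=4, cols=4, containers=("poisson", 1.5), params=params)
        series = []
        for _ in range(2):
            st = initialize_state(env, params, seed=99, init_eggs_per_container=20)
            out = []
            for _ in range(120):
                step_day(st, params)
                out.append((st.n_adult_females(), st.n_adult_males(), st.cohorts.total()))
            series.append(out)
        assert series[0] == series[1]

    def test_no_fk_carrying_adult_female_ever_exists(self, params):
        from fksim.releases import ReleasePlan, SiteSet, release_adults
        from fksim.genetics import StrainSpec

        env = make_env(rows=4, cols=4, containers=("poisson", 1.5), params=params)
        st = initialize_state(env, params, n_loci=1, seed=5, init_eggs_per_container=20)
        plan = ReleasePlan(stage="adults", pattern="homogeneous",
                           number_per_site_per_week=6, strain=StrainSpec(1),
                           start_day=60, duration_weeks=20)
        sites = SiteSet(houses=np.arange(16), active=np.ones(16, dtype=bool))
        for _ in range(220):
            if plan.is_release_day(st.day):
                release_adults(st, plan, sites)
            step_day(st, params)
            females = st.adults.sex == FEMALE
            assert np.all(st.adults.genotype[females] == 0)
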