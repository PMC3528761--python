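"""Release engine: site selection, adult/egg releases, insecticide, compliance."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from fksim.environment import GridSpec, build_environment
from fksim.genetics import StrainSpec, genotype_to_index
from fksim.params import default_params
from fksim.population import EGG, FEMALE, MALE, initialize_state, step_day
from fksim.releases import (
    InsecticidePlan,
    ReleasePlan,
    SiteSet,
    apply_insecticide,
    release_adults,
    release_eggs,
    release_ratio,
    select_sites,
    update_compliance,
)

from conftest import make_env


def full_city_env(seed=0):
    return build_environment(GridSpec(68, 36), containers_per_house=0, seed=seed)


class TestSelectSites:
    def test_random_10_percent_of_full_city_is_242(self):
        env = full_city_env()
        sites = select_sites(env, "random_sites", 0.10, seed=1)
        assert sites.n_sites == 242
        assert len(np.unique(sites.houses)) == 242

    def test_homogeneous_covers_every_house(self):
        env = full_city_env()
        sites = select_sites(env, "homogeneous")
        assert sites.n_sites == 2448

    def test_uniform_sublattice_count_and_spacing(self):
        env = full_city_env()
        sites = select_sites(env, "uniform_sites", 0.10)
        assert sites.n_sites == 242
        coords = np.column_stack(np.divmod(sites.houses, 36))
        min_spacing = pdist(coords, metric="chebyshev").min()
        assert min_spacing >= 2  # spacing ~ sqrt(2448/242) ~ 3.2

    def test_uniform_is_deterministic(self):
        env = full_city_env()
        s1 = select_sites(env, "uniform_sites", 0.10, seed=1)
        s2 = select_sites(env, "uniform_sites", 0.10, seed=999)
        assert np.array_equal(s1.houses, s2.houses)

    def test_zero_sites_rejected(self):
        env = build_environment(GridSpec(2, 2), containers_per_house=0, seed=0)
        with pytest.raises(ValueError):
            select_sites(env, "random_sites", 0.01)


class TestReleasePlan:
    def test_weekly_cadence(self):
        plan = ReleasePlan(start_day=100, duration_weeks=3, number_per_site_per_week=5)
        days = [d for d in range(150) if plan.is_release_day(d)]
        assert days == [100, 107, 114]

    def test_homogeneous_eggs_rejected(self):
        with pytest.raises(ValueError):
            ReleasePlan(stage="eggs", pattern="homogeneous")


class TestReleaseAdults:
    def _state(self, params, rows=5, cols=5):
        env = make_env(rows=rows, cols=cols, containers=0, params=params)
        return env, initialize_state(env, params, n_loci=1, seed=3)

    def test_all_males_at_site_when_fraction_zero(self, params):
        env, st = self._state(params)
        sites = SiteSet(houses=np.array([12]), active=np.array([True]))
        plan = ReleasePlan(number_per_site_per_week=100, start_day=0,
                           strain=StrainSpec(1), early_disperser_fraction=0.0)
        release_adults(st, plan, sites)
        a = st.adults
        assert len(a) == 100
        assert np.all(a.house == 12)
        assert np.all(a.released) and np.all(a.sex == MALE)
        assert np.all(a.genotype == genotype_to_index((2,)))

    def test_early_disperser_split_80_20(self, params):
        env, st = self._state(params)
        sites = SiteSet(houses=np.array([12]), active=np.array([True]))
        plan = ReleasePlan(number_per_site_per_week=100, start_day=0,
                           strain=StrainSpec(1), early_disperser_fraction=0.2)
        release_adults(st, plan, sites)
        at_site = (st.adults.house == 12).sum()
        assert at_site == 80
        assert len(st.adults) == 100

    def test_relocated_males_never_at_release_site(self, params):
        env, st = self._state(params)
        sites = SiteSet(houses=np.array([12]), active=np.array([True]))
        plan = ReleasePlan(number_per_site_per_week=1000, start_day=0,
                           strain=StrainSpec(1), early_disperser_fraction=1.0)
        release_adults(st, plan, sites)
        assert len(st.adults) == 1000
        assert np.all(st.adults.house != 12)

    def test_non_release_day_is_noop(self, params):
        env, st = self._state(params)
        sites = SiteSet(houses=np.array([0]), active=np.array([True]))
        plan = ReleasePlan(number_per_site_per_week=10, start_day=50)
        release_adults(st, plan, sites)
        assert len(st.adults) == 0


class TestReleaseEggs:
    def test_even_sex_split_in_new_shielded_container(self, params):
        env = make_env(rows=1, cols=1, containers=0, params=params)
        st = initialize_state(env, params, n_loci=3, seed=3)
        plan = ReleasePlan(stage="eggs", pattern="uniform_sites",
                           number_per_site_per_week=1600, start_day=0,
                           strain=StrainSpec(3))
        sites = SiteSet(houses=np.array([0]), active=np.array([True]))
        release_eggs(st, plan, sites, params)
        assert len(st.containers) == 1
        assert st.containers.shielded[0] and st.containers.removable[0]
        c = st.cohorts
        assert c.count[c.sex == MALE].sum() == 800
        assert c.count[c.sex == FEMALE].sum() == 800
        assert np.all(c.genotype == genotype_to_index((2, 2, 2)))

    def test_odd_number_split_as_evenly_as_possible(self, params):
        env = make_env(rows=1, cols=1, containers=0, params=params)
        st = initialize_state(env, params, n_loci=1, seed=3)
        plan = ReleasePlan(stage="eggs", pattern="uniform_sites",
                           number_per_site_per_week=101, start_day=0,
                           strain=StrainSpec(1))
        release_eggs(st, plan, SiteSet(houses=np.array([0]), active=np.array([True])), params)
        c = st.cohorts
        assert abs(c.count[c.sex == MALE].sum() - c.count[c.sex == FEMALE].sum()) == 1

    def test_only_males_emerge_and_container_is_removed(self, params):
        env = make_env(rows=1, cols=1, containers=0, params=params)
        st = initialize_state(env, params, n_loci=1, seed=3)
        plan = ReleasePlan(stage="eggs", pattern="uniform_sites",
                           number_per_site_per_week=400, start_day=0,
                           strain=StrainSpec(1))
        release_eggs(st, plan, SiteSet(houses=np.array([0]), active=np.array([True])), params)
        for _ in range(80):
            step_day(st, params)
            if len(st.cohorts) == 0:
                break
        assert len(st.cohorts) == 0
        assert not st.containers.alive[0]  # withdrawn once exhausted
        assert st.stats["emerged_females"] == 0
        assert st.stats["emerged_release_males"] > 0
        assert np.all(st.adults.sex[st.adults.released] == MALE)


class TestInsecticide:
    def test_multiplicative_mortality_with_full_coverage(self, params):
        env = make_env(rows=2, cols=2, containers=0, params=params)
        st = initialize_state(env, params, seed=3)
        n = 10_000
        st.add_adults(n, house=0, sex=MALE, genotype=0, weight=1.7)
        plan = InsecticidePlan(miss_probability=0.0, extra_daily_mortality=0.90,
                               end_day=10, duration_days=14)
        directive = apply_insecticide(st, plan)
        assert directive == (0.0, 0.90)
        step_day(st, params, insecticide=directive)
        expected = n * params.adult_male_survival * 0.1
        sd = np.sqrt(n * 0.077 * (1 - 0.077))
        assert abs(len(st.adults) - expected) < 3 * sd

    def test_missed_house_fraction(self, params):
        env = make_env(rows=40, cols=25, containers=0, params=params)
        p = params.replace(adult_male_survival=1.0, dispersal_probability=0.0)
        st = initialize_state(env, p, seed=3)
        n_houses = env.n_houses
        st.add_adults(n_houses, house=np.arange(n_houses), sex=MALE, genotype=0, weight=1.7)
        plan = InsecticidePlan(miss_probability=0.10, extra_daily_mortality=1.0, end_day=5)
        step_day(st, p, insecticide=apply_insecticide(st, plan))
        # survivors sat exactly in untreated houses
        frac_untreated = len(st.adults) / n_houses
        assert abs(frac_untreated - 0.10) < 3 * np.sqrt(0.09 / n_houses)

    def test_inactive_outside_window(self, params):
        env = make_env(rows=2, cols=2, containers=0, params=params)
        st = initialize_state(env, params, seed=3)
        plan = InsecticidePlan(end_day=10, duration_days=14)
        st.day = 11
        assert apply_insecticide(st, plan) is None
        st.day = 10
        assert apply_insecticide(st, plan) is not None

    def test_immatures_unaffected(self, params):
        env = make_env(rows=1, cols=1, containers=1, params=params)
        p = params.replace(egg_survival=1.0)
        st = initialize_state(env, p, seed=3, init_eggs_per_container=100)
        plan = InsecticidePlan(miss_probability=0.0, extra_daily_mortality=1.0, end_day=5)
        step_day(st, p, insecticide=apply_insecticide(st, plan))
        assert st.cohorts.total() == 100


class TestCompliance:
    def test_zero_decline_keeps_all_sites(self):
        sites = SiteSet(houses=np.arange(100), active=np.ones(100, dtype=bool))
        plan = ReleasePlan(compliance_decline_per_year=0.0)
        rng = np.random.Generator(np.random.PCG64(0))
        for week in range(104):
            update_compliance(sites, plan, week, rng)
        assert sites.active.all()

    def test_active_fraction_after_a_year_matches_annual_decline(self):
        n = 10_000
        sites = SiteSet(houses=np.arange(n), active=np.ones(n, dtype=bool))
        plan = ReleasePlan(compliance_decline_per_year=0.30)
        rng = np.random.Generator(np.random.PCG64(1))
        for week in range(52):
            update_compliance(sites, plan, week, rng)
        frac = sites.active.mean()
        assert abs(frac - 0.70) < 3 * np.sqrt(0.21 / n)

    def test_dropout_is_permanent(self):
        n = 500
        sites = SiteSet(houses=np.arange(n), active=np.ones(n, dtype=bool))
        plan = ReleasePlan(compliance_decline_per_year=0.50)
        rng = np.random.Generator(np.random.PCG64(2))
        dropped = np.zeros(n, dtype=bool)
        for week in range(104):
            update_compliance(sites, plan, week, rng)
            dropped |= ~sites.active
            assert not np.any(dropped & sites.active)  # never reactivates


class TestReleaseRatio:
    def test_homogeneous_ratio(self):
        # 5 males/house weekly against ~2 resident males per house
        assert release_ratio(5, 2448, 2 * 2448) == pytest.approx(2.5)

    def test_point_source_ratios(self):
        wild = 2 * 2448
        assert release_ratio(400, 242, wild) == pytest.approx(19.77, abs=0.01)
        assert release_ratio(1200, 242, wild) == pytest.approx(59.31, abs=0.01)

    def test_zero_wild_males_rejected(self):
        with pytest.raises(ValueError):
            release_ratio(5, 10, 0)
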