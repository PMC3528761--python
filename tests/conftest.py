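import numpy as np
import pytest

from fksim.environment import GridSpec, build_environment
from fksim.params import default_params
from fksim.population import initialize_state


@pytest.fixture(scope="session")
def params():
    return default_params()


def make_env(rows=3, cols=3, containers=1, n_days=600, seed=0, params=None,
             noise_sd=0.0, amplitude=0.0, food_input=None):
    """Small deterministic-weather city for unit tests."""
    p = params or default_params()
    return build_environment(
        GridSpec(rows, cols),
        containers_per_house=containers,
        container_profile={
            "capacity": p.container_capacity_l,
            "water_level": p.container_water_l,
            "food_input": p.container_food_input_mg if food_input is None else food_input,
            "food_amount": p.container_initial_food_mg,
        },
        weather_params={"n_days": n_days, "mean": 26.0, "amplitude": amplitude,
                        "noise_sd": noise_sd},
        seed=seed,
    )


@pytest.fixture
def small_env(params):
    return make_env(params=params)


@pytest.fixture
def small_state(small_env, params):
    return initialize_state(small_env, params, seed=1)
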