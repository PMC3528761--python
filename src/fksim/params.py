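"""Model parameters and their default calibration.

All tunable demographic and ecological constants live in
``config/defaults.yaml`` (shipped with the package); :class:`ModelParams`
is a flat, typed view of them.  The uncertainty analysis varies fields of
this object directly (e.g. ``adult_female_survival``, ``fk_male_survival``,
``dispersal_probability``, stage durations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = ["ModelParams", "default_params", "load_params"]


@dataclass
class ModelParams:
    # nominal daily survival probabilities
    egg_survival: float
    larva_survival: float
    pupa_survival: float
    adult_female_survival: float
    adult_male_survival: float
    fk_male_survival: float

    # adult movement
    dispersal_probability: float

    # development (median stage durations at 27 C, days)
    egg_days: float
    larva_days: float
    pupa_days: float
    gonotrophic_days: float
    first_gono_extra_days: float
    female_mating_age_days: int
    ramp: float
    egg_hatch_daily_max: float
    briere_t0: float
    briere_tmax: float

    # reproduction
    eggs_per_batch: int

    # larval growth / food competition
    hatch_weight_mg: float
    pupation_weight_mg: float
    min_pupation_weight_mg: float
    adult_weight_fraction: float
    released_adult_weight_mg: float
    feeding_coeff: float
    maintenance_fraction: float
    starvation_weight_mg: float
    starvation_mortality: float
    max_larva_days: int

    # resident containers
    container_capacity_l: float
    container_water_l: float
    container_food_input_mg: float
    food_decay: float
    container_initial_food_mg: float

    # release containers (never food-limited)
    release_capacity_l: float
    release_water_l: float
    release_food_input_mg: float
    release_initial_food_mg: float

    # default synthetic city
    containers_per_house_poisson: float
    weather_mean_c: float
    weather_amplitude_c: float
    weather_noise_sd_c: float

    def __post_init__(self) -> None:
        for name in (
            "egg_survival",
            "larva_survival",
            "pupa_survival",
            "adult_female_survival",
            "adult_male_survival",
            "fk_male_survival",
            "dispersal_probability",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("egg_days", "larva_days", "pupa_days", "gonotrophic_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    # -- temperature response --------------------------------------------
    def thermal_factor(self, temperature: float) -> float:
        """Briere-type unimodal thermal scaling, normalized to 1 at 27 C.

        Development rates are ``factor / stage_days``.  The exact shape is
        immaterial for the near-constant tropical default weather; it just
        provides a smooth, biologically plausible response.
        """
        t0, tmax = self.briere_t0, self.briere_tmax

        def b(t: float) -> float:
            if t <= t0 or t >= tmax:
                return 0.0
            return t * (t - t0) * float(np.sqrt(tmax - t))

        return b(temperature) / b(27.0)

    def dev_rate(self, stage_days: float, temperature: float) -> float:
        return self.thermal_factor(temperature) / stage_days


def _flatten(doc: dict) -> dict:
    s = doc["survival"]
    d = doc["development"]
    g = doc["larval_growth"]
    c = doc["containers"]
    rc = doc["release_container"]
    env = doc["environment"]
    return dict(
        egg_survival=s["egg"],
        larva_survival=s["larva"],
        pupa_survival=s["pupa"],
        adult_female_survival=s["adult_female"],
        adult_male_survival=s["adult_male"],
        fk_male_survival=s["fk_male"],
        dispersal_probability=doc["dispersal_probability"],
        egg_days=d["egg_days"],
        larva_days=d["larva_days"],
        pupa_days=d["pupa_days"],
        gonotrophic_days=d["gonotrophic_days"],
        first_gono_extra_days=d["first_gono_extra_days"],
        female_mating_age_days=int(d["female_mating_age_days"]),
        ramp=d["ramp"],
        egg_hatch_daily_max=d["egg_hatch_daily_max"],
        briere_t0=d["briere_t0"],
        briere_tmax=d["briere_tmax"],
        eggs_per_batch=int(doc["reproduction"]["eggs_per_batch"]),
        hatch_weight_mg=g["hatch_weight_mg"],
        pupation_weight_mg=g["pupation_weight_mg"],
        min_pupation_weight_mg=g["min_pupation_weight_mg"],
        adult_weight_fraction=g["adult_weight_fraction"],
        released_adult_weight_mg=g["released_adult_weight_mg"],
        feeding_coeff=g["feeding_coeff"],
        maintenance_fraction=g["maintenance_fraction"],
        starvation_weight_mg=g["starvation_weight_mg"],
        starvation_mortality=g["starvation_mortality"],
        max_larva_days=int(g["max_larva_days"]),
        container_capacity_l=c["capacity_l"],
        container_water_l=c["water_l"],
        container_food_input_mg=c["food_input_mg"],
        food_decay=c["food_decay"],
        container_initial_food_mg=c["initial_food_mg"],
        release_capacity_l=rc["capacity_l"],
        release_water_l=rc["water_l"],
        release_food_input_mg=float(rc["food_input_mg"]),
        release_initial_food_mg=float(rc["initial_food_mg"]),
        containers_per_house_poisson=env["containers_per_house_poisson"],
        weather_mean_c=env["weather_mean_c"],
        weather_amplitude_c=env["weather_amplitude_c"],
        weather_noise_sd_c=env["weather_noise_sd_c"],
    )


def load_params(path) -> ModelParams:
    """Load a full parameter set from a YAML file (same layout as defaults)."""
    with open(path) as fh:
        return ModelParams(**_flatten(yaml.safe_load(fh)))


def default_params() -> ModelParams:
    text = resources.files("fksim.config").joinpath("defaults.yaml").read_text()
    return ModelParams(**_flatten(yaml.safe_load(text)))
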