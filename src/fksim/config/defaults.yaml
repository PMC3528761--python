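# Default calibration for the synthetic Iquitos-like environment.
# These constants are calibration choices, not measurements: together they
# pin the net demographic rates so that (i) the default city equilibrates
# near ~2 resident adult males per house and (ii) a never-food-limited
# container seeded with 1600 eggs yields ~600 emerging adult males.

survival:                 # nominal daily survival probabilities
  egg: 0.99
  larva: 0.972
  pupa: 0.992
  adult_female: 0.77
  adult_male: 0.77
  fk_male: 0.77           # released FK males (uncertainty-analysis knob)

dispersal_probability: 0.30   # per adult per day, to a random orthogonal neighbor

development:              # median stage durations (days) at 27 C
  egg_days: 3.0
  larva_days: 7.0         # minimum, food-unlimited
  pupa_days: 2.0
  gonotrophic_days: 5.0   # oviposition cycle length at 27 C
  first_gono_extra_days: 2.0  # extra maturation before the first oviposition
  female_mating_age_days: 1   # females become receptive this many days after emergence
  ramp: 0.15              # transition spread (fraction of stage) around completion
  egg_hatch_daily_max: 0.35   # cap on daily hatch probability (short egg bank)
  briere_t0: 10.0         # lower thermal limit (C)
  briere_tmax: 40.0       # upper thermal limit (C)

reproduction:
  eggs_per_batch: 47

larval_growth:            # simplified food/weight competition model
  hatch_weight_mg: 0.05
  pupation_weight_mg: 2.0         # target weight under unlimited food
  min_pupation_weight_mg: 1.0     # stunted larvae may pupate this small
  adult_weight_fraction: 0.85   # adult weight as fraction of pupal weight
  released_adult_weight_mg: 1.0 # released males carry the field wild-type mean weight
  feeding_coeff: 0.30           # demand = coeff * W^(2/3) mg/day per larva
  maintenance_fraction: 0.10    # intake fraction below which weight declines
  starvation_weight_mg: 0.045   # below this weight: extra daily mortality
  starvation_mortality: 0.40
  max_larva_days: 40            # stalled larvae die beyond this age

containers:               # resident container template
  capacity_l: 20.0
  water_l: 15.0
  food_input_mg: 2.35     # per day; the main density-dependence calibration
  food_decay: 0.40        # daily fraction of uneaten food lost
  initial_food_mg: 30.0

release_container:        # optimal-nutrient egg-release container
  capacity_l: 50.0
  water_l: 40.0
  food_input_mg: 1.0e5
  initial_food_mg: 1.0e6

environment:              # default synthetic city
  containers_per_house_poisson: 1.5
  weather_mean_c: 26.0
  weather_amplitude_c: 1.0
  weather_noise_sd_c: 0.5
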