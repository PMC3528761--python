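# Methods

## Scope and intent

`fksim` evaluates release strategies for female-killing (FK) transgenic
*Aedes aegypti* strains on a synthetic city. It is a deliberately
simplified cousin of detailed entomological simulators (CIMSiM-family
models): immatures are cohorts inside individual containers, adults are
individuals inside houses, and every stochastic event — survival,
development, mating, oviposition, dispersal, release logistics — runs on
one seeded random stream per replicate, so every result is exactly
reproducible. Dengue transmission, immigration from outside the grid,
container thermodynamics (sun exposure, evaporation) and rain-driven
water levels are out of scope.

## Synthetic environment

A city is a `rows × cols` grid of houses (default full-city size
68×36 = 2448; most experiments use reduced grids). Containers are
assigned per house i.i.d. from a configurable distribution (default
Poisson with mean 1.5); each carries a capacity (L), a constant water
level, a daily food input (mg/day) and a food stock. Daily mean
temperature is an annual sinusoid plus Gaussian noise (default
26 ± 1 °C, σ = 0.5 °C — tropical, weakly seasonal).

**Heterogeneity (Φ transform).** Each house independently becomes
high-producing with probability 1/Φ (every container duplicated Φ−1
times, deep copies with fresh identifiers) or low-producing with
probability 1−1/Φ (each container kept with probability 1/(Φ−1)). The
expected city-wide container count is invariant and Φ = 2 is the identity.
On a homogeneous 1-container baseline, exact enumeration of the
two-outcome distribution gives a coefficient of variation of
√(((Φ−1)²+1)/Φ − 1): ≈ 82% at Φ = 3 and ≈ 155% at Φ = 5 — the enumeration
(`heterogeneity_count_distribution`) is the reference the stochastic
transform is tested against.

## Population dynamics

One day applies, in fixed order: (1) adult survival (plus insecticide
excess mortality), (2) nominal immature survival, (3) container food and
larval weight update, (4) development and stage transitions, (5) mating,
(6) oviposition, (7) dispersal. Total individuals change only through
death, emergence and oviposition.

**Development.** Each stage has a median duration at 27 °C (egg 3 d,
larva 7 d minimum, pupa 2 d) scaled by a Brière-type unimodal thermal
response normalized to 1 at 27 °C (limits 10–40 °C). A cohort transitions
stochastically over a ramp of width ±0.15 of the stage around completion,
which spreads a single cohort's transitions over ~2–3 days. Egg hatch
additionally requires standing water and is capped at a daily probability
of 0.35, creating a short egg bank.

**Larval competition.** Per-larva demand is `feeding_coeff · W^(2/3)`
(mg/day); a container's realized intake fraction is `u = F/(F + D)` for
stock F and total demand D, so per-capita intake falls as biomass grows
and saturates as food becomes abundant. Weight changes in proportion to
`(u − u_m)/(1 − u_m)` (maintenance fraction `u_m = 0.1`; negative below
it); development advances as `√` of the same factor, so crowded larvae
mature late **and small** (minimum pupation weight 1.0 mg vs. a 2.0 mg
food-unlimited target), which propagates to adult body weight and hence
to mating success. Larvae whose weight falls below 0.045 mg, or whose
intake deficit is extreme, suffer extra daily mortality (0.4·deficit);
larvae older than 40 d die. Uneaten food decays at 40%/day, so an empty
container cannot bank an unbounded food surplus: a fresh 47-egg batch
already competes with itself. This within-batch ("sibling") competition
deliberately limits the low-density compensation reserve of the resident
population — the feature that makes sterile-male-style suppression
winnable at realistic release ratios.

**Adults.** Daily survival 0.77 for both sexes (mean lifespan
1/0.23 ≈ 4.35 days); the survival of released FK males is a separate knob
(default equal). Each adult moves with probability 0.30/day to a
uniformly chosen existing orthogonal neighbor (edge/corner houses have
3/2 neighbors; no wraparound) — identical for both sexes and for released
males. One exception: a gravid female whose batch is overdue because her
house has no usable container moves with certainty (oviposition-site
seeking); without it, houses emptied of containers — common after the Φ
transform — silently absorb most of the population's fecundity.

**Mating and reproduction.** Females are strictly monogamous; each
unmated female in a house with ≥ 1 male draws a mate with probability
proportional to male weight (times an FK mating-competitiveness
multiplier, default 1) and stores his genotype for life; in a male-free
house she retries the next day. Females become receptive the day
after emergence; the first gonotrophic cycle then takes 5 + 2 days
(cycle + blood-feeding/maturation delay), subsequent cycles 5 days, all
thermally scaled. A batch is 47 eggs laid into one
non-shielded, water-holding container of the current house chosen with
probability proportional to capacity; offspring genotypes are multinomial
draws from the Mendelian cross, sex assigned 50:50 at laying. With a
4.35-day mean lifespan and a first oviposition at age ≈ 8 days, a
female's expected lifetime fecundity is ≈ 8 eggs — low-margin demography typical of this
species' field populations, and the second deliberate limit on the
compensation reserve.

**Genetics.** Genotypes are per-locus FK copy numbers at 1–4 unlinked
loci. Any emerging female with ≥ 1 copy dies on her emergence day
(penetrance is a knob fixed at 1); males are unaffected. The optional
per-locus fitness cost c (relative fitnesses 1, (1−c)^½, (1−c),
multiplicative across loci) is charged as a viability multiplier f^⅓ at
each of the three immature transitions, compounding to f across
development — a documented choice; the cost's mechanistic locus
(viability vs. fecundity vs. mating) is genuinely open.

## Interventions

* **Adult releases** — weekly, homozygous FK males, at every house
  (homogeneous) or at ~10% of houses (uniform sublattice or random
  draw; a 68×36 grid yields exactly 242 sites from the 22×11 sublattice
  geometry, and the random pattern uses the same count). A
  deterministically rounded early-disperser fraction of each cohort is
  placed at houses drawn uniformly among all houses except the release
  site. Released males carry the *field* wild-type mean adult weight
  (1.0 mg): under weight-proportional mating, giving them the
  optimal-rearing weight (1.7 mg) instead would grant a ~1.8× mating
  advantage over field-reared residents and qualitatively change the
  strategy comparisons; the assumption of equal mating competitiveness
  pins their weight to the resident mean.
* **Egg releases** — weekly, one fresh shielded container per active
  site with effectively unlimited food, seeded half male / half female
  homozygous FK eggs; only males emerge; the container is withdrawn once
  its cohort is exhausted.
* **Insecticide** — a 14-day adulticide window ending the day before
  releases start; each house misses treatment with daily probability 0.1;
  treated-house adults suffer an extra 0.9 death probability after
  nominal survival; immatures are unaffected.
* **Compliance decline** — each active site drops out permanently each
  week with hazard q, (1−q)⁵² = 1 − annual decline, so the expected
  active fraction after one year equals the annual retention. The
  geometric (rather than linear) decline is a documented choice.

## Outcome metrics

*Elimination*: no immatures outside shielded release containers and no
adults other than currently-alive released males — externally replenished
individuals do not count against elimination of the *resident*
population. Elimination is absorbing (all females are gone), so
replicates stop early once it occurs. *Time to 90% reduction*: first day
after release start with adult-female count ≤ 10% of the 21-day
pre-release mean; replicates that never reach it are excluded from
averages and counted. *Suppression efficacy*: percent reduction of
adult-female density between the 21-day pre-release window and days
200–400 after release start. *Elimination proportions* carry binomial
standard errors √(p̂(1−p̂)/n).

## Calibration

All constants live in `src/fksim/config/defaults.yaml`. The net rates are
pinned by three emergent targets, in this order:

1. **Egg-to-adult survival under optimal nutrients** — a shielded
   container seeded with 1600 FK eggs yields ≈ 600 emerging adult males
   (and no females) over a few days; this fixes the nominal immature
   survivals (0.99 / 0.972 / 0.992 per day for egg / larva / pupa).
2. **Equilibrium density** — the default city equilibrates near 2
   resident adult males per house; this fixes the container food input
   (2.35 mg/day) at the default container density.
3. **Elimination thresholds** — weekly homogeneous releases eliminate
   the resident population in all replicates at ≈ 8 males/house/week for
   the 1-construct strain and fewer for the 3-construct strain; this
   pins the fecundity side (47 eggs/batch, 5-day cycle, 1-day receptive age plus 2-day
   first-cycle delay) within field-plausible ranges.

Because (1) caps the immature survival ceiling and (2) fixes the
equilibrium, the suppression-resistance of the population is governed by
the low-density compensation reserve — lifetime fecundity times the
survival of a lone batch in a resident container — which the sibling
competition and the first-cycle delay hold near 3–4, the regime in which
release ratios of a few to one are decisive.

## Uncertainty analysis

First-order variance contributions of the demographic parameters
(adult survivals, FK male survival, dispersal probability, stage
durations; ±20% ranges, probabilities capped at 0.995) to suppression
efficacy are estimated with **RBD-FAST**: every parameter follows the
same triangular search curve under independent random permutations of
the sampling points; a parameter's index is the spectral power at the
curve frequency and its first 6 harmonics after re-sorting the outputs
along that parameter's curve, over the total sample variance, with the
standard `S − λ(1−S)`, `λ = 2M/N` bias correction, and bootstrap CIs over
replicate designs. The estimator is validated against closed-form Sobol
indices (additive linear and Ishigami functions) in the test suite; the
classical multi-frequency eFAST variant was rejected because its
per-curve total-variance denominator is biased by interactions that a
single search curve explores poorly. The simulator wiring fixes the
released:wild male ratio at 2.5 (measured at the end of a 200-day
burn-in) and runs on a reduced grid (12×12, ~520 runs by default); a full
5000-run analysis is a matter of configuration, not code.

## Problem sizes

Default experiment sizes are chosen for a single CPU: reduced 20×20
grids for threshold sweeps (1-year burn-in + 3 control years, 30
replicates, ascending level scan stopping a level at its first failed
replicate and the scan at the first all-eliminate level — both shortcuts
leave the reported minimal level unchanged), 12×12 grids for scenario
orderings, and analytic functions for estimator validation. Full-city
(68×36) runs are supported by configuration.

## Known limitations

* The larval competition scheme is a two-parameter caricature of
  Gilpin–McClelland dynamics; absolute densities and thresholds inherit
  its calibration rather than field data.
* Under the Φ transform the realized resident population shrinks (the
  concentration of containers converts food into adults less efficiently
  in this scheme), so at a *fixed absolute release number* elimination
  can become easier with heterogeneity — the opposite of the
  fixed-number comparison at city scale with survey-calibrated container
  counts. At a *matched released:wild ratio* heterogeneity impedes
  elimination as expected (high-producing houses act as refuges), and
  that is the form the property suite tests.
* The all-replicates elimination criterion sits in the upper tail of the
  elimination-probability curve, and on reduced grids that curve is
  shallow (few independent refuge clusters), so the measured thresholds
  of the 1- and 3-construct strains compress toward each other: the
  ordering (3-construct ≤ 1-construct) is robust, but the 3-construct
  absolute threshold comes out higher relative to the 1-construct one
  than a full-city run would give.
* Constant water levels remove egg-bank dynamics driven by rainfall;
  real populations are more elimination-resistant than this model.
* Synthetic weather is near-constant; strongly seasonal settings would
  need the thermal response exercised over a wider range.
* A replicate's sites, weather noise and demography share one master
  seed; cross-scenario comparisons in the test suite use common random
  numbers deliberately.
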