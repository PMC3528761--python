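"""Synthetic study area: house grid, water-holding containers, weather.

The simulated city is a rectangular grid of premises ("houses"), each of
which holds zero or more water-holding containers in which immature
mosquitoes develop.  The default parameterization emulates a tropical,
weakly seasonal Amazonian city: a near-constant daily mean temperature and
moderate among-house heterogeneity in container counts.

Among-house heterogeneity can be amplified with the Φ-transform
(:func:`apply_heterogeneity`): each house independently becomes
"high-producing" with probability 1/Φ (its containers are replicated Φ−1
times) or "low-producing" with probability 1−1/Φ (each container is kept
with probability 1/(Φ−1)).  The transform preserves the expected city-wide
container count while raising its among-house variance; Φ=2 is the
identity.
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "ContainerSpec",
    "WeatherSeries",
    "HeterogeneitySettings",
    "Environment",
    "build_environment",
    "apply_heterogeneity",
    "generate_weather",
    "heterogeneity_count_distribution",
]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid of premises; one house per cell."""

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.rows}x{self.cols}")

    @property
    def n_houses(self) -> int:
        return self.rows * self.cols

    def house_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"({row}, {col}) not on {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def coords(self, house: int) -> tuple[int, int]:
        return divmod(int(house), self.cols)

    def neighbor_table(self) -> tuple[np.ndarray, np.ndarray]:
        """4-orthogonal (von Neumann) neighbors, no wraparound.

        Returns ``(table, counts)`` where ``table[h, :counts[h]]`` lists the
        flat indices of house ``h``'s existing neighbors (edge and corner
        houses have 3 and 2).
        """
        n = self.n_houses
        table = np.full((n, 4), -1, dtype=np.int64)
        counts = np.zeros(n, dtype=np.int64)
        for h in range(n):
            r, c = divmod(h, self.cols)
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < self.rows and 0 <= cc < self.cols:
                    table[h, counts[h]] = rr * self.cols + cc
                    counts[h] += 1
        return table, counts


@dataclass
class ContainerSpec:
    """One water-holding container attached to a house.

    ``shielded`` marks release containers that ovipositing wild females
    cannot access; resident containers are never shielded.  ``removable``
    marks externally supplied containers that are withdrawn once their
    cohort is exhausted.
    """

    container_id: int
    house: int
    capacity: float  # litres
    water_level: float  # litres
    food_input: float  # mg/day
    food_amount: float = 0.0  # mg
    shielded: bool = False
    removable: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.water_level <= self.capacity):
            raise ValueError("water_level must lie in [0, capacity]")
        if self.food_amount < 0:
            raise ValueError("food_amount must be >= 0")
        if self.food_input < 0:
            raise ValueError("food_input must be >= 0")


@dataclass
class WeatherSeries:
    """Daily mean temperature series (°C)."""

    temperature: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not np.all(np.isfinite(self.temperature)):
            raise ValueError("temperatures must be finite")

    def __len__(self) -> int:
        return len(self.temperature)

    def __getitem__(self, day: int) -> float:
        return float(self.temperature[day])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": np.arange(len(self.temperature)), "temperature": self.temperature}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path)
        return cls(df["temperature"].to_numpy())


@dataclass(frozen=True)
class HeterogeneitySettings:
    """Settings for the Φ container-redistribution transform."""

    phi: int
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if int(self.phi) != self.phi or self.phi < 2:
            raise ValueError(f"phi must be an integer >= 2, got {self.phi!r}")


@dataclass
class Environment:
    """A synthetic city: grid, containers and weather."""

    grid: GridSpec
    containers: list[ContainerSpec]
    weather: WeatherSeries

    def __post_init__(self) -> None:
        n = self.grid.n_houses
        for c in self.containers:
            if not (0 <= c.house < n):
                raise ValueError(f"container {c.container_id} house {c.house} off grid")

    @property
    def n_houses(self) -> int:
        return self.grid.n_houses

    def containers_per_house(self) -> np.ndarray:
        counts = np.zeros(self.grid.n_houses, dtype=np.int64)
        for c in self.containers:
            counts[c.house] += 1
        return counts

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "grid": {"rows": self.grid.rows, "cols": self.grid.cols},
            "containers": [asdict(c) for c in self.containers],
            "weather": {"temperature": self.weather.temperature.tolist()},
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Environment":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            try:
                doc = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    doc = json.load(fh)
        return cls(
            grid=GridSpec(**doc["grid"]),
            containers=[ContainerSpec(**c) for c in doc["containers"]],
            weather=WeatherSeries(np.asarray(doc["weather"]["temperature"])),
        )


# ---------------------------------------------------------------------------
# construction


def _draw_counts(spec, n_houses: int, rng: np.random.Generator) -> np.ndarray:
    """Per-house container counts from a distribution spec.

    Accepted forms: a nonnegative integer (fixed count), ``("poisson", mean)``
    or ``{"poisson": mean}``, or an explicit sequence of counts to resample
    from (an empirical survey list).
    """
    if isinstance(spec, (int, np.integer)):
        if spec < 0:
            raise ValueError("container count must be >= 0")
        return np.full(n_houses, int(spec), dtype=np.int64)
    if isinstance(spec, dict):
        spec = next(iter(spec.items()))
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "poisson":
        mean = float(spec[1])
        if mean < 0:
            raise ValueError("Poisson mean must be >= 0")
        return rng.poisson(mean, size=n_houses).astype(np.int64)
    counts = np.asarray(list(spec), dtype=np.int64)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("empirical count list must be non-empty and nonnegative")
    return rng.choice(counts, size=n_houses, replace=True)


def build_environment(
    grid_spec: GridSpec,
    containers_per_house=("poisson", 1.0),
    container_profile: dict | None = None,
    weather_params: dict | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> Environment:
    """Assemble a synthetic city.

    Parameters
    ----------
    grid_spec:
        Grid of premises; one house per cell.
    containers_per_house:
        Per-house container count distribution (see :func:`_draw_counts`);
        counts are drawn i.i.d. across houses.
    container_profile:
        Template for resident containers: ``capacity``, ``water_level``,
        ``food_input``, ``food_amount`` and optional ``capacity_jitter``
        (lognormal sigma applied multiplicatively to capacity).
    weather_params:
        ``n_days``, ``mean``, ``amplitude``, ``noise_sd`` for
        :func:`generate_weather`.
    seed:
        Master seed; the whole construction is deterministic given it.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    counts_ss, jitter_ss, weather_ss = ss.spawn(3)
    rng = np.random.Generator(np.random.PCG64(counts_ss))

    profile = {
        "capacity": 20.0,
        "water_level": 15.0,
        "food_input": 3.0,
        "food_amount": 30.0,
        "capacity_jitter": 0.0,
    }
    if container_profile:
        profile.update(container_profile)

    wparams = {"n_days": 365, "mean": 26.0, "amplitude": 1.0, "noise_sd": 0.5}
    if weather_params:
        wparams.update(weather_params)

    counts = _draw_counts(containers_per_house, grid_spec.n_houses, rng)
    total = int(counts.sum())
    jrng = np.random.Generator(np.random.PCG64(jitter_ss))
    if profile["capacity_jitter"] > 0:
        factors = np.exp(jrng.normal(0.0, profile["capacity_jitter"], size=total))
    else:
        factors = np.ones(total)

    containers: list[ContainerSpec] = []
    cid = itertools.count()
    k = 0
    for house, n_c in enumerate(counts):
        for _ in range(n_c):
            cap = profile["capacity"] * factors[k]
            containers.append(
                ContainerSpec(
                    container_id=next(cid),
                    house=house,
                    capacity=cap,
                    water_level=min(profile["water_level"], cap),
                    food_input=profile["food_input"],
                    food_amount=profile["food_amount"],
                )
            )
            k += 1

    weather = generate_weather(
        n_days=wparams["n_days"],
        mean=wparams["mean"],
        amplitude=wparams["amplitude"],
        noise_sd=wparams["noise_sd"],
        seed=weather_ss,
    )
    return Environment(grid=grid_spec, containers=containers, weather=weather)


def apply_heterogeneity(env: Environment, settings: HeterogeneitySettings) -> Environment:
    """Amplify among-house productivity heterogeneity with the Φ-transform.

    Each house independently becomes high-producing with probability 1/Φ
    (each of its containers appears Φ−1 times) or low-producing with
    probability 1−1/Φ (each container kept with probability 1/(Φ−1)).
    Expected total container count is unchanged; Φ=2 is the identity.
    Duplicated containers are deep copies with fresh identifiers.
    """
    phi = int(settings.phi)
    ss = (
        settings.seed
        if isinstance(settings.seed, np.random.SeedSequence)
        else np.random.SeedSequence(settings.seed)
    )
    rng = np.random.Generator(np.random.PCG64(ss))

    n = env.grid.n_houses
    high = rng.random(n) < 1.0 / phi
    keep_p = 1.0 / (phi - 1)

    next_id = max((c.container_id for c in env.containers), default=-1) + 1
    new_containers: list[ContainerSpec] = []
    for c in env.containers:
        if high[c.house]:
            for rep in range(phi - 1):
                dup = copy.deepcopy(c)
                if rep > 0:
                    dup.container_id = next_id
                    next_id += 1
                new_containers.append(dup)
        else:
            if rng.random() < keep_p:
                new_containers.append(copy.deepcopy(c))
    return Environment(grid=env.grid, containers=new_containers, weather=env.weather)


def heterogeneity_count_distribution(phi: int, base_count: int = 1):
    """Exact per-house count distribution after the Φ-transform.

    For a homogeneous baseline of ``base_count`` containers per house the
    post-transform count is ``base_count*(Φ−1)`` with probability 1/Φ, else
    Binomial(``base_count``, 1/(Φ−1)).  Returns ``(values, probs)`` by
    brute-force enumeration — the reference used to check the empirical
    mean/CV of :func:`apply_heterogeneity`.
    """
    from scipy import stats

    if phi < 2:
        raise ValueError("phi must be >= 2")
    support: dict[int, float] = {}
    support[base_count * (phi - 1)] = 1.0 / phi
    binom = stats.binom(base_count, 1.0 / (phi - 1))
    for k in range(base_count + 1):
        support[k] = support.get(k, 0.0) + (1.0 - 1.0 / phi) * float(binom.pmf(k))
    values = np.array(sorted(support))
    probs = np.array([support[v] for v in values])
    return values, probs


def generate_weather(
    n_days: int,
    mean: float = 26.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.5,
    seed: int | np.random.SeedSequence | None = 0,
) -> WeatherSeries:
    """Daily mean temperature: annual sinusoid around ``mean`` plus noise."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    days = np.arange(n_days)
    temps = mean + amplitude * np.sin(2.0 * np.pi * days / 365.25)
    if noise_sd > 0:
        temps = temps + rng.normal(0.0, noise_sd, size=n_days)
    return WeatherSeries(temps)
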