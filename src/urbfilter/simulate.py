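"""Synthetic point-count surveys with known urban-filtering ground truth.

The generator emulates a multi-city urban/periurban survey design: each city
has its own regional species pool (a lognormal or log-series rank-abundance
distribution), per-cell bird totals follow a Poisson law modulated by
vegetation cover, and species counts within a cell are multinomial draws
from the city pool.  Urban cells re-weight the pool by a per-species urban
multiplier: "avoider" species are down-weighted by the filter strength,
"exploiter" species are up-weighted, and a configurable subset of the
exploiters are exotic species with a strong urban boost (emulating the
dominance of introduced urban exploiters such as the house sparrow).

Because every species carries a ground-truth fate class and multiplier, the
downstream null model's classifications can be scored against the truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import largest_remainder, substream
from .tables import DIET_GUILDS, HABITAT_GUILDS

#: Default species richness per diet guild (sums to 54), patterned on the
#: guild composition of a south-temperate urban/periurban avifauna:
#: insectivores dominate, followed by granivores and omnivores.
DEFAULT_DIET_WEIGHTS = {
    "insectivore": 27,
    "granivore": 12,
    "omnivore": 5,
    "frugivore": 4,
    "carnivore": 3,
    "nectarivore": 2,
    "carrion": 1,
}
#: Default species richness per preferred-habitat guild (sums to 54).
DEFAULT_HABITAT_WEIGHTS = {
    "open": 18,
    "generalist": 14,
    "forest": 12,
    "water_wetland": 10,
}

FATES = ("avoider", "tolerant", "exploiter")


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic survey generator.

    Defaults mirror a three-city design with 110 urban and 50 periurban
    point-count cells per city and a 54-species regional avifauna.
    ``filter_strength`` f in [0, 1] sets the avoiders' urban multiplier to
    1 - f; exploiters get 1 + f, and exotic exploiters get ``exotic_boost``.
    """

    n_cities: int = 3
    n_urban_cells: int = 110
    n_periurban_cells: int = 50
    n_species: int = 54
    abundance_model: str = "lognormal"  # or "logseries"
    lognormal_sigma: float = 1.0
    logseries_p: float = 0.95
    avoider_fraction: float = 0.3
    exploiter_fraction: float = 0.1
    filter_strength: float = 0.8
    exotic_boost: float = 20.0
    n_exotics: int = 3
    mean_count_per_cell: float = 12.0
    veg_effect: float = 0.5
    shared_pool: bool = False
    diet_weights: dict = field(default_factory=lambda: dict(DEFAULT_DIET_WEIGHTS))
    habitat_weights: dict = field(default_factory=lambda: dict(DEFAULT_HABITAT_WEIGHTS))
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if min(self.n_cities, self.n_urban_cells, self.n_periurban_cells) < 1:
            raise ConfigError("city and cell counts must be >= 1")
        if not 0 <= self.filter_strength <= 1:
            raise ConfigError("filter_strength must lie in [0, 1]")
        if self.avoider_fraction < 0 or self.exploiter_fraction < 0:
            raise ConfigError("fate fractions must be nonnegative")
        if self.avoider_fraction + self.exploiter_fraction > 1:
            raise ConfigError("avoider_fraction + exploiter_fraction must be <= 1")
        if self.exotic_boost < 1:
            raise ConfigError("exotic_boost must be >= 1")
        if self.mean_count_per_cell <= 0:
            raise ConfigError("mean_count_per_cell must be positive")
        if self.abundance_model not in ("lognormal", "logseries"):
            raise ConfigError("abundance_model must be 'lognormal' or 'logseries'")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def _city_names(n: int) -> list[str]:
    return [f"city{i + 1}" for i in range(n)]


def _species_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"sp{i + 1:0{width}d}" for i in range(n)]


def _assign_categorical(rng, names, weights, allowed) -> pd.Series:
    w = [weights.get(g, 0.0) for g in allowed]
    counts = largest_remainder(w, len(names))
    labels = np.repeat(list(allowed), counts)
    return pd.Series(rng.permutation(labels), index=names)


def _draw_abundances(rng, config) -> np.ndarray:
    if config.abundance_model == "lognormal":
        x = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=config.n_species)
    else:
        x = stats.logser.rvs(config.logseries_p, size=config.n_species, random_state=rng).astype(float)
    return x / x.sum()


def generate_pool(config: GeneratorConfig):
    """Draw per-city species pools, traits and ground-truth fate classes.

    Returns
    -------
    pools : DataFrame, cities x species relative abundances (rows sum to 1).
    traits : DataFrame indexed by species (diet_guild, habitat_guild, origin).
    truth : DataFrame indexed by species (fate_class, urban_multiplier).
    """
    config.validate()
    species = _species_names(config.n_species)
    cities = _city_names(config.n_cities)

    trait_rng = substream(config.seed, "traits")
    diet = _assign_categorical(trait_rng, species, config.diet_weights, DIET_GUILDS)
    habitat = _assign_categorical(
        trait_rng, species, config.habitat_weights, HABITAT_GUILDS
    )

    # fate classes: floor + largest-remainder over (avoider, exploiter, tolerant)
    fate_rng = substream(config.seed, "fates")
    n_av, n_ex, _ = largest_remainder(
        [
            config.avoider_fraction,
            config.exploiter_fraction,
            1 - config.avoider_fraction - config.exploiter_fraction,
        ],
        config.n_species,
    )
    order = fate_rng.permutation(config.n_species)
    fate = pd.Series("tolerant", index=species, dtype=object)
    fate.iloc[order[:n_av]] = "avoider"
    exploiters = order[n_av : n_av + n_ex]
    fate.iloc[exploiters] = "exploiter"

    origin = pd.Series("native", index=species, dtype=object)
    n_exotic = min(config.n_exotics, n_ex)
    origin.iloc[exploiters[:n_exotic]] = "exotic"

    # All multipliers collapse to 1 at filter_strength = 0, so that setting
    # is a true no-filtering null (urban and periurban share one sampling law).
    mult = pd.Series(1.0, index=species)
    mult[fate == "avoider"] = 1.0 - config.filter_strength
    mult[fate == "exploiter"] = 1.0 + config.filter_strength
    mult[(fate == "exploiter") & (origin == "exotic")] = (
        1.0 + config.filter_strength * (config.exotic_boost - 1.0)
    )

    traits = pd.DataFrame(
        {"diet_guild": diet, "habitat_guild": habitat, "origin": origin}
    )
    traits.index.name = "species_id"
    truth = pd.DataFrame({"fate_class": fate, "urban_multiplier": mult})
    truth.index.name = "species_id"

    if config.shared_pool:
        shared = _draw_abundances(substream(config.seed, "pool", "shared"), config)
        pools = pd.DataFrame([shared] * len(cities), index=cities, columns=species)
    else:
        pools = pd.DataFrame(
            [
                _draw_abundances(substream(config.seed, "pool", city), config)
                for city in cities
            ],
            index=cities,
            columns=species,
        )
    pools.index.name = "city"
    return pools, traits, truth


def generate_study(config: GeneratorConfig):
    """Generate a full synthetic survey: counts, cell metadata, traits, truth.

    Per cell, vegetation cover is Beta-distributed (urban cells
    stochastically barer than periurban ones), the bird total is
    Poisson(mean_count_per_cell * exp(veg_effect * (veg - 0.5))), and species
    counts are a single multinomial draw from the city pool -- re-weighted by
    the urban multipliers and renormalised in urban cells.

    Returns ``(survey, cells, traits, truth)``.
    """
    config.validate()
    pools, traits, truth = generate_pool(config)
    mult = truth["urban_multiplier"].to_numpy()

    frames, meta = [], []
    for city in pools.index:
        rng = substream(config.seed, "study", city)
        p = pools.loc[city].to_numpy()
        w_urban = p * mult
        w_urban = w_urban / w_urban.sum()

        for habitat, n_cells, weights, a, b in (
            ("urban", config.n_urban_cells, w_urban, 2.0, 6.0),
            ("periurban", config.n_periurban_cells, p, 6.0, 4.0),
        ):
            veg = rng.beta(a, b, size=n_cells)
            lam = config.mean_count_per_cell * np.exp(
                config.veg_effect * (veg - 0.5)
            )
            totals = rng.poisson(lam)
            counts = rng.multinomial(totals, weights)
            ids = [f"{city}_{habitat[0]}{i + 1:03d}" for i in range(n_cells)]
            frames.append(
                pd.DataFrame(counts, index=ids, columns=pools.columns)
            )
            meta.append(
                pd.DataFrame(
                    {"city": city, "habitat": habitat, "veg_cover": veg}, index=ids
                )
            )
    survey = pd.concat(frames)
    survey.index.name = "cell_id"
    cells = pd.concat(meta)
    cells.index.name = "cell_id"
    return survey, cells, traits, truth
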