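"""Herbivore species registry and census tables.

The study system is a fenced, predator-free temperate grazing reserve holding
Heck cattle, Konik horses, red deer and wintering geese (greylag + barnacle).
Species are described by body mass (kg), metabolic guild (which allometric
daily-energy-expenditure curve applies) and the fraction of time the animals
forage inside the reserve.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

LARGE_HERBIVORE = "large_herbivore"
GOOSE = "goose"

#: Census seasons. Ungulates are counted each October (pre-winter, the count
#: relevant to November dung sampling) and each May (post winter mortality).
#: Geese additionally get a December-April wintering average.
SEASONS = ("October", "May", "winter_average")


@dataclass(frozen=True)
class HerbivoreSpecies:
    """One herbivore population's static attributes.

    Parameters
    ----------
    name : str
        Species label used throughout census / diet tables.
    body_mass : float
        Mean live body weight of one individual, kg. Must be positive.
    guild : str
        ``"large_herbivore"`` or ``"goose"``; selects the allometric DEE curve.
    residence_fraction : float
        Fraction of time spent foraging in the reserve, in (0, 1]. Geese
        commute to surrounding farmland and get 0.5; ungulates are fenced
        in permanently and get 1.0.
    """

    name: str
    body_mass: float
    guild: str = LARGE_HERBIVORE
    residence_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError(f"body_mass must be > 0, got {self.body_mass}")
        if self.guild not in (LARGE_HERBIVORE, GOOSE):
            raise ValueError(f"unknown guild {self.guild!r}")
        if not 0 < self.residence_fraction <= 1:
            raise ValueError(
                f"residence_fraction must be in (0, 1], got {self.residence_fraction}"
            )


#: Default registry with the reserve's populations and their mean body masses.
DEFAULT_SPECIES: dict[str, HerbivoreSpecies] = {
    "cattle": HerbivoreSpecies("cattle", 420.0, LARGE_HERBIVORE, 1.0),
    "horse": HerbivoreSpecies("horse", 375.0, LARGE_HERBIVORE, 1.0),
    "red_deer": HerbivoreSpecies("red_deer", 120.0, LARGE_HERBIVORE, 1.0),
    "greylag_goose": HerbivoreSpecies("greylag_goose", 3.3, GOOSE, 0.5),
    "barnacle_goose": HerbivoreSpecies("barnacle_goose", 1.9, GOOSE, 0.5),
}

#: Dung of the two goose species cannot be told apart in the field, so diet
#: samples carry the pooled label.
GOOSE_POOL_LABEL = "geese"

#: The four dung-sampled diet groups.
DIET_SPECIES = ("cattle", "horse", "red_deer", GOOSE_POOL_LABEL)

CENSUS_COLUMNS = ("species", "year", "season", "count")


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    """Validate a census table (species, year, season, count).

    Counts must be non-negative and each (species, year, season) unique.
    Returns the table unchanged on success.
    """
    missing = set(CENSUS_COLUMNS) - set(census.columns)
    if missing:
        raise ValueError(f"census table missing columns: {sorted(missing)}")
    if (census["count"] < 0).any():
        raise ValueError("census counts must be non-negative")
    bad_season = set(census["season"]) - set(SEASONS)
    if bad_season:
        raise ValueError(f"unknown census seasons: {sorted(bad_season)}")
    dup = census.duplicated(subset=["species", "year", "season"])
    if dup.any():
        raise ValueError("duplicate (species, year, season) census entries")
    return census


def census_counts(
    census: pd.DataFrame, season: str = "October", species: list[str] | None = None
) -> pd.DataFrame:
    """Pivot a census to a year x species count table for one season."""
    validate_census(census)
    sub = census[census["season"] == season]
    if species is not None:
        sub = sub[sub["species"].isin(species)]
    return sub.pivot(index="year", columns="species", values="count").sort_index()
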