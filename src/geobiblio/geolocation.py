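"""Offline resolution of author addresses to (city, country).

An address like ``"Helsinki University Hospital, Helsinki, Finland"`` is
tokenized on commas; the rightmost token that canonicalizes to a known
country decides the country, after which the longest token naming a city of
that country (case-insensitive, punctuation-stripped) decides the city.
This replaces an online geocoding service with a deterministic gazetteer
lookup: precision over recall, and reproducible by construction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Gazetteer",
    "GeoLocation",
    "CountryInfo",
    "load_gazetteer",
    "default_gazetteer",
    "default_populations",
    "geolocate_address",
    "normalize_country",
    "country_known",
    "map_continent",
    "join_population",
    "CONTINENTS",
    "COUNTRY_ALIASES",
]

# canonical country -> continent; the Americas merge North and South America
CONTINENTS: dict[str, str] = {
    "USA": "Americas", "Canada": "Americas", "Brazil": "Americas",
    "Mexico": "Americas", "Argentina": "Americas", "Chile": "Americas",
    "Colombia": "Americas", "Peru": "Americas",
    "UK": "Europe", "France": "Europe", "Germany": "Europe",
    "Netherlands": "Europe", "Switzerland": "Europe", "Sweden": "Europe",
    "Denmark": "Europe", "Italy": "Europe", "Spain": "Europe",
    "Belgium": "Europe", "Norway": "Europe", "Finland": "Europe",
    "Austria": "Europe", "Ireland": "Europe", "Greece": "Europe",
    "Portugal": "Europe", "Poland": "Europe", "Iceland": "Europe",
    "China": "Asia", "Japan": "Asia", "Israel": "Asia",
    "South Korea": "Asia", "India": "Asia", "Singapore": "Asia",
    "Thailand": "Asia", "Pakistan": "Asia", "Saudi Arabia": "Asia",
    "Bangladesh": "Asia", "Taiwan": "Asia", "Malaysia": "Asia",
    "South Africa": "Africa", "Kenya": "Africa", "Nigeria": "Africa",
    "Egypt": "Africa", "Ethiopia": "Africa", "Uganda": "Africa",
    "Australia": "Oceania", "New Zealand": "Oceania",
}

# alias (lowercased) -> canonical country
COUNTRY_ALIASES: dict[str, str] = {
    "united states": "USA", "united states of america": "USA", "usa": "USA",
    "u.s.a.": "USA", "us": "USA", "u.s.": "USA", "america": "USA",
    "united kingdom": "UK", "uk": "UK", "u.k.": "UK", "great britain": "UK",
    "england": "UK", "scotland": "UK", "wales": "UK", "northern ireland": "UK",
    "holland": "Netherlands", "the netherlands": "Netherlands",
    "peoples r china": "China", "people's republic of china": "China",
    "pr china": "China", "republic of korea": "South Korea",
    "korea": "South Korea", "korea, south": "South Korea", "s korea": "South Korea",
    "republic of ireland": "Ireland", "deutschland": "Germany",
    "republic of south africa": "South Africa", "rsa": "South Africa",
    "kingdom of saudi arabia": "Saudi Arabia", "uae": "United Arab Emirates",
}
# canonical names resolve to themselves, case-insensitively
COUNTRY_ALIASES.update({c.lower(): c for c in CONTINENTS})

_PUNCT = re.compile(r"[^\w\s]")


def _clean(token: str) -> str:
    return re.sub(r"\s+", " ", _PUNCT.sub(" ", token)).strip()


def normalize_country(name: str) -> str:
    """Canonicalize a country name; unknown names pass through verbatim."""
    if not name or not name.strip():
        raise ValueError("empty country name")
    cleaned = name.strip()
    return COUNTRY_ALIASES.get(cleaned.lower(), COUNTRY_ALIASES.get(_clean(cleaned).lower(), cleaned))


def country_known(name: str) -> bool:
    """True if the name canonicalizes to a country in the continent table."""
    return normalize_country(name) in CONTINENTS


def map_continent(country: str) -> str:
    """Continent label for a canonical country name."""
    canonical = normalize_country(country)
    try:
        return CONTINENTS[canonical]
    except KeyError:
        raise KeyError(f"no continent mapping for country {country!r}") from None


@dataclass(frozen=True)
class GeoLocation:
    """Resolved location for one address string."""

    country: str | None
    city: str | None = None
    lat: float | None = None
    lng: float | None = None
    resolution: str = "unresolved"  # city | country | unresolved

    def __post_init__(self) -> None:
        if self.resolution == "city" and (self.city is None or self.lat is None):
            raise ValueError("city-level resolution requires city and coordinates")
        if self.resolution == "country" and self.country is None:
            raise ValueError("country-level resolution requires a country")


@dataclass
class Gazetteer:
    """Offline city/country lookup table."""

    entries: pd.DataFrame  # columns: city, country, lat, lng, pop, capital

    def __post_init__(self) -> None:
        # lookup: country -> {lowercased city: row index}
        self._cities: dict[str, dict[str, int]] = {}
        for idx, row in self.entries.iterrows():
            self._cities.setdefault(row["country"], {})[row["city"].lower()] = idx

    @property
    def countries(self) -> set[str]:
        return set(self._cities)

    def cities_of(self, country: str) -> dict[str, int]:
        return self._cities.get(country, {})

    def lookup(self, city: str, country: str) -> pd.Series | None:
        idx = self.cities_of(country).get(city.lower())
        return None if idx is None else self.entries.loc[idx]

    def __len__(self) -> int:
        return len(self.entries)


REQUIRED_GAZETTEER_COLUMNS = ("city", "country", "lat", "lng", "pop", "capital")


def load_gazetteer(source: str | Path | pd.DataFrame) -> Gazetteer:
    """Load and canonicalize a gazetteer CSV.

    Duplicate (city, country) rows collapse to the highest-population entry;
    rows with out-of-range coordinates are rejected with a warning.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    for col in REQUIRED_GAZETTEER_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"gazetteer is missing column {col!r}")
    df["country"] = df["country"].map(normalize_country)
    df["city"] = df["city"].astype(str).str.strip()
    bad = ~(df["lat"].between(-90, 90) & df["lng"].between(-180, 180))
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} gazetteer row(s) with out-of-range coordinates: "
            f"{df.loc[bad, 'city'].tolist()}",
            stacklevel=2,
        )
        df = df[~bad]
    df = (
        df.sort_values("pop", ascending=False)
        .drop_duplicates(subset=["city", "country"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    return Gazetteer(df)


def default_gazetteer() -> Gazetteer:
    """The packaged ~160-city gazetteer covering the 32 study countries."""
    with resources.as_file(resources.files("geobiblio.data") / "gazetteer.csv") as p:
        return load_gazetteer(p)


def default_populations() -> pd.DataFrame:
    """Packaged national population table (World Bank style, year 2019)."""
    with resources.as_file(resources.files("geobiblio.data") / "populations.csv") as p:
        return pd.read_csv(p)


def _within_one_edit(a: str, b: str) -> bool:
    """Levenshtein distance <= 1, for the optional fuzzy city match."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:  # one substitution
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # one insertion into the shorter string
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def geolocate_address(address: str, gz: Gazetteer, fuzzy: bool = False) -> GeoLocation:
    """Resolve one raw address string against a gazetteer.

    Pure function of (address, gazetteer); unresolvable addresses return
    ``resolution="unresolved"`` rather than raising.  ``fuzzy=True`` lets a
    city token match at edit distance 1 when no exact match exists.
    """
    if not address or not address.strip():
        raise ValueError("empty address")
    tokens = [t for t in (seg.strip() for seg in address.split(",")) if t]
    country = None
    country_pos = None
    for pos in range(len(tokens) - 1, -1, -1):
        candidate = normalize_country(tokens[pos])
        if candidate in gz.countries:
            country, country_pos = candidate, pos
            break
    if country is None:
        return GeoLocation(country=None, resolution="unresolved")

    cities = gz.cities_of(country)
    best: str | None = None
    for pos, tok in enumerate(tokens):
        if pos == country_pos:
            continue
        cleaned = _clean(tok).lower()
        if cleaned in cities and (best is None or len(cleaned) > len(best)):
            best = cleaned
    if best is None and fuzzy:
        for pos, tok in enumerate(tokens):
            if pos == country_pos:
                continue
            cleaned = _clean(tok).lower()
            # deterministic: cities in gazetteer order, first hit wins per length
            for name in cities:
                if _within_one_edit(cleaned, name) and (best is None or len(name) > len(best)):
                    best = name
    if best is None:
        return GeoLocation(country=country, resolution="country")
    row = gz.entries.loc[cities[best]]
    return GeoLocation(
        country=country,
        city=row["city"],
        lat=float(row["lat"]),
        lng=float(row["lng"]),
        resolution="city",
    )


@dataclass(frozen=True)
class CountryInfo:
    country: str
    continent: str | None
    population: float | None  # persons; None when missing from the table

    @property
    def missing_population(self) -> bool:
        return self.population is None


def _wide_year_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if str(c).strip().isdigit()]


def join_population(
    countries: Iterable[str],
    table: str | Path | pd.DataFrame,
    year: int | None = None,
) -> list[CountryInfo]:
    """Attach national populations (and continents) to a country list.

    ``table`` is either long format (columns ``country, population``) or
    World Bank wide format (one column per year); for the latter ``year``
    selects the column.  Countries absent from the table are returned with
    ``population=None`` and a warning.
    """
    df = table.copy() if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    if "country" not in df.columns:
        raise ValueError("population table is missing column 'country'")
    df["country"] = df["country"].map(normalize_country)

    if "population" in df.columns:
        pop = df.set_index("country")["population"]
    else:
        years = _wide_year_columns(df)
        if not years:
            raise ValueError("population table has neither 'population' nor year columns")
        col = str(year) if year is not None else years[-1]
        if col not in df.columns:
            raise ValueError(f"population table has no column for year {year}")
        pop = df.set_index("country")[col]

    out: list[CountryInfo] = []
    missing: list[str] = []
    for name in countries:
        canonical = normalize_country(name)
        continent = CONTINENTS.get(canonical)
        value = pop.get(canonical)
        if value is None or pd.isna(value):
            missing.append(canonical)
            out.append(CountryInfo(canonical, continent, None))
        else:
            out.append(CountryInfo(canonical, continent, float(value)))
    if missing:
        warnings.warn(f"no population for: {missing}; excluded from normalized metrics", stacklevel=2)
    return out
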