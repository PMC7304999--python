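"""Domain types and validated CSV input/output for transect butterfly surveys.

The data model mirrors a line-transect study of butterfly communities along a
canopy-cover gradient: repeated surveys at fixed sites, each detection recorded
with its perpendicular distance from the transect line (for distance sampling),
a taxon code (species where possible, family/genus otherwise), and a flag for
whether the individual was directly under tree or shrub canopy.

Three input tables drive the pipeline:

``observations.csv``
    one row per detection event —
    ``site_id,year,day_of_year,survey_round,taxon_code,species_level,distance_m,count,under_canopy``
``sites.csv``
    one row per site —
    ``site_id,x_m,y_m,transect_length_m,canopy_cover_pct,habitat,fire2,fire15,veg_short,veg_tall,litter,habitat_diversity,developed_pct,agriculture_pct``
``species.csv``
    one row per species —
    ``species_code,family,natureserve_rank``

Readers return validated :class:`pandas.DataFrame` objects (the canonical
in-memory container throughout the package); the frozen dataclasses below are
typed record constructors that apply the same invariants row-wise.

A replica of the published species table (61 species: densities, counts,
habitat of maximum indicator value, effective strip widths) ships with the
package as a read-only fixture, see :func:`load_table2_fixture`.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "SchemaError",
    "Observation",
    "Site",
    "SpeciesTrait",
    "read_observations",
    "write_observations",
    "read_sites",
    "write_sites",
    "read_species_traits",
    "write_species_traits",
    "load_table2_fixture",
    "genus_of",
]

#: Habitat classes of the canopy-cover gradient, in gradient order.
HABITATS = ("open", "savanna", "woodland", "scrub", "forest")

#: NatureServe G/T rank grammar, e.g. "G5", "G3G4", "G5T2".
RANK_PATTERN = re.compile(r"^G([1-5])(?:G([1-5]))?(?:T([1-5]))?$")

OBSERVATION_COLUMNS = [
    "site_id", "year", "day_of_year", "survey_round", "taxon_code",
    "species_level", "distance_m", "count", "under_canopy",
]
SITE_COLUMNS = [
    "site_id", "x_m", "y_m", "transect_length_m", "canopy_cover_pct",
    "habitat", "fire2", "fire15", "veg_short", "veg_tall", "litter",
    "habitat_diversity", "developed_pct", "agriculture_pct",
]
SPECIES_COLUMNS = ["species_code", "family", "natureserve_rank"]

_TABLE2_SHA256 = "ec298a581f726df96ba90e04e80936a01a556f30dcfde96ea842c3eec965eae2"


class SchemaError(ValueError):
    """A table or record violates the documented schema or an invariant."""


@dataclass(frozen=True)
class Observation:
    """One detection event on a transect survey."""

    site_id: str
    year: int
    day_of_year: int
    survey_round: int
    taxon_code: str
    resolved_to_species: bool
    perpendicular_distance: float  # meters from the transect line
    count: float = 1.0             # fractional after apportionment
    under_canopy: bool = False

    def __post_init__(self) -> None:
        if self.perpendicular_distance < 0:
            raise SchemaError(
                f"perpendicular_distance must be >= 0, got "
                f"{self.perpendicular_distance} for taxon {self.taxon_code}")
        if not self.count > 0:
            raise SchemaError(f"count must be > 0, got {self.count}")
        if not 1 <= self.day_of_year <= 366:
            raise SchemaError(
                f"day_of_year must be in [1, 366], got {self.day_of_year}")


@dataclass(frozen=True)
class Site:
    """A survey site: one 500-m transect (or two 250-m halves) plus attributes."""

    site_id: str
    x: float
    y: float
    transect_length: float   # meters
    canopy_cover: float      # percent, [0, 100]
    habitat: str
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transect_length > 0:
            raise SchemaError(
                f"transect_length must be > 0, got {self.transect_length}")
        if not 0 <= self.canopy_cover <= 100:
            raise SchemaError(
                f"canopy_cover must be in [0, 100], got {self.canopy_cover}")
        if self.habitat not in HABITATS:
            raise SchemaError(
                f"unknown habitat {self.habitat!r}; expected one of {HABITATS}")


@dataclass(frozen=True)
class SpeciesTrait:
    """Taxonomy plus NatureServe conservation rank for one species."""

    species_code: str
    family: str
    natureserve_rank_raw: str

    def __post_init__(self) -> None:
        if RANK_PATTERN.match(self.natureserve_rank_raw) is None:
            raise SchemaError(
                f"unparsable NatureServe rank {self.natureserve_rank_raw!r} "
                f"for species {self.species_code}")


def genus_of(species_code: str) -> str:
    """Genus part of a species code.

    Binomial codes use the first whitespace-separated token
    (``"Papilio polyxenes"`` -> ``"Papilio"``); synthetic codes use the part
    before the first underscore (``"gen03_sp17"`` -> ``"gen03"``).
    """
    if " " in species_code:
        return species_code.split()[0]
    return species_code.split("_")[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check(df: pd.DataFrame, mask: pd.Series, fieldname: str, why: str, path) -> None:
    bad = df.index[mask]
    if len(bad):
        raise SchemaError(
            f"{path}: row {bad[0] + 2} (1-based, incl. header): "
            f"field {fieldname!r} {why} (value {df.loc[bad[0], fieldname]!r})")


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observations table.

    Returns a DataFrame with columns :data:`OBSERVATION_COLUMNS`;
    ``species_level``/``under_canopy`` are booleans, ``count`` is float
    (fractional counts arise after apportionment of family-level records).
    Rows whose ``species_level`` flag is false carry a higher-taxon code
    (family or genus) in ``taxon_code``.
    """
    df = pd.read_csv(path)
    _require_columns(df, OBSERVATION_COLUMNS, path)
    df = df[OBSERVATION_COLUMNS].copy()
    for col in ("year", "day_of_year", "survey_round"):
        df[col] = df[col].astype(int)
    df["distance_m"] = df["distance_m"].astype(float)
    df["count"] = df["count"].astype(float)
    _check(df, df["distance_m"] < 0, "distance_m", "must be >= 0", path)
    _check(df, ~(df["count"] > 0), "count", "must be > 0", path)
    _check(df, ~df["day_of_year"].between(1, 366), "day_of_year",
           "must be in [1, 366]", path)
    df["species_level"] = df["species_level"].astype(bool)
    df["under_canopy"] = df["under_canopy"].astype(bool)
    df["site_id"] = df["site_id"].astype(str)
    df["taxon_code"] = df["taxon_code"].astype(str)
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    """Write an observations table in the canonical CSV dialect.

    Booleans are stored as 0/1; floats use shortest round-trippable decimal
    notation so that reader∘writer is the identity on valid files.
    """
    out = df[OBSERVATION_COLUMNS].copy()
    out["species_level"] = out["species_level"].astype(int)
    out["under_canopy"] = out["under_canopy"].astype(int)
    out.to_csv(path, index=False, float_format="%.10g")


def read_sites(path) -> pd.DataFrame:
    """Read and validate a site-attribute table (one row per site)."""
    df = pd.read_csv(path)
    _require_columns(df, SITE_COLUMNS, path)
    df = df[SITE_COLUMNS].copy()
    df["site_id"] = df["site_id"].astype(str)
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate site_id {dup!r}")
    _check(df, ~(df["transect_length_m"] > 0), "transect_length_m",
           "must be > 0", path)
    _check(df, ~df["canopy_cover_pct"].between(0, 100), "canopy_cover_pct",
           "must be in [0, 100]", path)
    _check(df, ~df["habitat"].isin(HABITATS), "habitat",
           f"must be one of {HABITATS}", path)
    return df


def write_sites(df: pd.DataFrame, path) -> None:
    df[SITE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_species_traits(path) -> pd.DataFrame:
    """Read and validate a species-trait table (code, family, NatureServe rank)."""
    df = pd.read_csv(path)
    _require_columns(df, SPECIES_COLUMNS, path)
    df = df[SPECIES_COLUMNS].copy()
    df["species_code"] = df["species_code"].astype(str)
    if df["species_code"].duplicated().any():
        dup = df.loc[df["species_code"].duplicated(), "species_code"].iloc[0]
        raise SchemaError(f"{path}: duplicate species_code {dup!r}")
    bad = ~df["natureserve_rank"].astype(str).str.match(RANK_PATTERN)
    _check(df, bad, "natureserve_rank", "does not match the G/T rank grammar",
           path)
    return df


def write_species_traits(df: pd.DataFrame, path) -> None:
    df[SPECIES_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged 61-species summary table.

    Columns: ``family, common_name, species_name, mean_density`` (ha^-1),
    ``density_se, density_rank, counts, max_group`` (habitat with the highest
    indicator value), ``max_group_significance`` ("*" p<0.05, "***" p<0.001,
    empty otherwise), ``esw`` (effective strip width, m), and ``esw_pooled``
    (True where the ESW was shared across a pooled species group).

    Raises
    ------
    SchemaError
        If the packaged file fails its checksum (corrupted installation).
    """
    ref = resources.files("canopycomm") / "data" / "table2_fixture.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE2_SHA256:
        raise SchemaError(
            f"table2_fixture.csv checksum mismatch: {digest} != {_TABLE2_SHA256}")
    import io
    df = pd.read_csv(io.BytesIO(raw), keep_default_na=False,
                     dtype={"max_group_significance": str})
    df["esw_pooled"] = df["esw_pooled"].astype(bool)
    return df
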