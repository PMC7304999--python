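"""Distance-sampling engine: from raw transect counts to per-hectare densities.

Counts along a line transect under-represent true abundance because
detectability decays with perpendicular distance from the line, and decays at
species-specific rates (a large swallowtail is visible much farther than a
small skipper).  Distance sampling corrects for this by fitting a detection
function g(x) to the observed perpendicular distances and converting counts to
densities over an *effective strip width* (ESW), the half-width at which the
number of individuals detected beyond the ESW equals the number missed within
it:

    ESW = integral_0^w g(x) dx,    g(x) = exp(-x^2 / (2 sigma^2))

with the half-normal detection key used throughout this package.  For an
untruncated fit (w = infinity) the maximum-likelihood estimate has the closed
form sigma_hat = sqrt(sum(x_i^2)/n) and ESW = sigma * sqrt(pi/2).

Species with too few detections to support their own fit are pooled with
taxonomically similar species (same genus, else same family, else a global
pool) and share the pooled fit's ESW.  Records identified only to a higher
taxon are apportioned to species in proportion to same-site, same-day
identified counts before densities are computed.

Density per survey and species follows the standard line-transect estimator

    D = 10^4 * n / (2 * L * ESW)   [individuals ha^-1]

with n the (possibly fractional) count, L the transect length in meters and
ESW in meters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import erf

from .core import genus_of

__all__ = [
    "DetectionFit",
    "pool_species",
    "fit_halfnormal",
    "effective_strip_width",
    "apportion_unidentified",
    "estimate_densities",
    "fit_detection_groups",
    "DensityTableMeta",
    "META_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Metadata columns preceding the species density columns in a density table.
META_COLUMNS = ["site_id", "survey_round", "year", "day_of_year"]

#: Kept for interface clarity in type hints: a density table is a DataFrame
#: whose first columns are META_COLUMNS and whose remaining columns are
#: per-species densities in individuals per hectare.
DensityTableMeta = META_COLUMNS


class DegenerateFitError(ValueError):
    """Raised when a detection function cannot be estimated from the data."""


@dataclass(frozen=True)
class DetectionFit:
    """A fitted half-normal detection function for a (pooled) species group."""

    group_id: str
    member_species: tuple[str, ...]
    sigma: float                  # half-normal scale, meters
    truncation: float             # w; may be math.inf
    esw: float                    # effective strip width, meters
    n_detections: int
    log_likelihood: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DegenerateFitError(f"sigma must be > 0, got {self.sigma}")


def pool_species(observations: pd.DataFrame, traits: pd.DataFrame,
                 min_detections: int = 30) -> dict[str, str]:
    """Assign every species to a detection-fit group.

    Species with at least ``min_detections`` species-level detections stand
    alone.  Sparser species are pooled with the nearest taxonomic neighbours
    that jointly clear the threshold: congeners first, then confamilials, and
    finally a single global pool.  The result is a true partition: a mapping
    ``species_code -> group_id`` covering every species in ``traits``.
    """
    obs = observations[observations["species_level"]]
    counts = obs.groupby("taxon_code")["count"].sum()
    known = set(traits["species_code"])
    unknown = set(counts.index) - known
    if unknown:
        raise KeyError(
            f"species absent from traits table: {sorted(unknown)[:5]}")

    n_det = {sp: float(counts.get(sp, 0.0)) for sp in traits["species_code"]}
    genus = {sp: genus_of(sp) for sp in n_det}
    family = dict(zip(traits["species_code"], traits["family"]))

    assignment: dict[str, str] = {}
    for sp, n in n_det.items():
        if n >= min_detections:
            assignment[sp] = sp
            continue
        congeners = [s for s in n_det if genus[s] == genus[sp]]
        if sum(n_det[s] for s in congeners) >= min_detections and len(congeners) > 1:
            assignment[sp] = f"genus:{genus[sp]}"
            continue
        confam = [s for s in n_det if family[s] == family[sp]]
        if sum(n_det[s] for s in confam) >= min_detections and len(confam) > 1:
            assignment[sp] = f"family:{family[sp]}"
            continue
        assignment[sp] = "global"
    return assignment


def fit_halfnormal(distances, truncation: float = math.inf) -> DetectionFit:
    """Maximum-likelihood half-normal detection fit.

    Maximizes ``prod g(x_i) / integral_0^w g`` over sigma.  With no
    truncation this reduces to the closed form ``sigma = sqrt(mean(x^2))``;
    with finite ``w`` the truncated likelihood is maximized numerically.

    Raises :class:`DegenerateFitError` for empty input or all-zero distances.
    """
    x = np.asarray(distances, dtype=float)
    if x.size == 0:
        raise DegenerateFitError("no distances supplied")
    if np.any(x < 0):
        raise ValueError("distances must be nonnegative")
    if math.isfinite(truncation) and np.any(x > truncation):
        raise ValueError("distances exceed the truncation distance")
    sumsq = float(np.sum(x ** 2))
    n = x.size
    if sumsq == 0.0:
        raise DegenerateFitError("all distances are zero; sigma is degenerate")

    if math.isinf(truncation):
        sigma = math.sqrt(sumsq / n)
    else:
        def nll(log_sigma: float) -> float:
            s = math.exp(log_sigma)
            esw = _esw(s, truncation)
            return n * math.log(esw) + sumsq / (2 * s * s)

        res = minimize_scalar(nll, bounds=(math.log(1e-4), math.log(1e4)),
                              method="bounded",
                              options={"xatol": 1e-10})
        sigma = math.exp(res.x)

    esw = _esw(sigma, truncation)
    loglik = -n * math.log(esw) - sumsq / (2 * sigma * sigma)
    return DetectionFit(group_id="", member_species=(), sigma=sigma,
                        truncation=truncation, esw=esw, n_detections=n,
                        log_likelihood=loglik)


def _esw(sigma: float, truncation: float) -> float:
    # closed form via the error function; equals sigma*sqrt(pi/2) untruncated
    if math.isinf(truncation):
        return sigma * math.sqrt(math.pi / 2)
    return sigma * math.sqrt(math.pi / 2) * erf(truncation / (sigma * math.sqrt(2)))


def effective_strip_width(fit: DetectionFit) -> float:
    """ESW of a fitted detection function: ``integral_0^w exp(-x^2/2 sigma^2) dx``."""
    return _esw(fit.sigma, fit.truncation)


def fit_detection_groups(observations: pd.DataFrame, traits: pd.DataFrame,
                         min_detections: int = 30,
                         truncation: float = math.inf) -> dict[str, DetectionFit]:
    """Pool species and fit one half-normal per group.

    Returns a mapping ``species_code -> DetectionFit``.  Members of a pooled
    group share the identical fit object, hence the identical ESW, and that
    fit is estimated from the distances of *all* species in the pooling scope
    (every congener for a genus pool, every confamilial for a family pool),
    so a sparse species borrows detectability information from its abundant
    relatives.
    """
    assignment = pool_species(observations, traits, min_detections)
    genus = {sp: genus_of(sp) for sp in assignment}
    family = dict(zip(traits["species_code"], traits["family"]))
    obs = observations[observations["species_level"]]
    fits_by_group: dict[str, DetectionFit] = {}
    out: dict[str, DetectionFit] = {}
    for group_id in sorted(set(assignment.values())):
        members = tuple(sorted(s for s, g in assignment.items() if g == group_id))
        if group_id.startswith("genus:"):
            g = group_id.split(":", 1)[1]
            scope = [sp for sp in assignment if genus[sp] == g]
        elif group_id.startswith("family:"):
            f = group_id.split(":", 1)[1]
            scope = [sp for sp in assignment if family[sp] == f]
        elif group_id == "global":
            scope = list(assignment)
        else:
            scope = list(members)
        dist = obs.loc[obs["taxon_code"].isin(scope), "distance_m"].to_numpy()
        if dist.size == 0:
            continue  # species never observed; no densities will be needed
        base = fit_halfnormal(dist, truncation)
        fit = DetectionFit(group_id=group_id, member_species=members,
                           sigma=base.sigma, truncation=base.truncation,
                           esw=base.esw, n_detections=base.n_detections,
                           log_likelihood=base.log_likelihood)
        fits_by_group[group_id] = fit
        for sp in members:
            out[sp] = fit
    return out


def apportion_unidentified(observations: pd.DataFrame,
                           traits: pd.DataFrame) -> pd.DataFrame:
    """Apportion higher-taxon records to species.

    Each record not resolved to species has its count split among the species
    of that taxon (family, or genus) identified *at the same site on the same
    day*, proportionally to their identified counts.  Records with no
    identified same-site/same-day candidate are dropped and logged.  Counts
    are conserved: total before = total after + total dropped.

    Returns a new observations frame containing only species-level rows
    (original ones plus fractional apportioned increments, appended as rows
    that inherit the unidentified record's distance and canopy flag).
    """
    known_species = set(traits["species_code"])
    families = dict(zip(traits["species_code"], traits["family"]))
    genera = {sp: genus_of(sp) for sp in known_species}

    ident = observations[observations["species_level"]]
    unident = observations[~observations["species_level"]]
    if unident.empty:
        return observations.copy()

    # candidate species per higher-taxon code
    taxon_members: dict[str, list[str]] = {}
    for code in unident["taxon_code"].unique():
        members = [sp for sp in known_species
                   if families[sp] == code or genera[sp] == code]
        if not members:
            raise KeyError(f"higher taxon {code!r} has no candidate species "
                           "in the traits table")
        taxon_members[code] = members

    # identified counts per (site, year, day, species)
    key_cols = ["site_id", "year", "day_of_year"]
    ident_counts = (ident.groupby(key_cols + ["taxon_code"])["count"].sum())

    new_rows = []
    dropped = 0.0
    for _, row in unident.iterrows():
        members = taxon_members[row["taxon_code"]]
        key = (row["site_id"], row["year"], row["day_of_year"])
        present = {}
        for sp in members:
            c = ident_counts.get(key + (sp,), 0.0)
            if c > 0:
                present[sp] = c
        if not present:
            dropped += row["count"]
            logger.info(
                "dropped %.3g unidentified %s at site %s day %s: no identified "
                "candidates that site/day", row["count"], row["taxon_code"],
                row["site_id"], row["day_of_year"])
            continue
        total = sum(present.values())
        for sp, c in present.items():
            r = row.to_dict()
            r["taxon_code"] = sp
            r["species_level"] = True
            r["count"] = row["count"] * c / total
            new_rows.append(r)

    if dropped:
        logger.info("apportionment dropped %.3g individuals in total", dropped)
    out = pd.concat([ident, pd.DataFrame(new_rows, columns=observations.columns)],
                    ignore_index=True) if new_rows else ident.copy().reset_index(drop=True)
    return out


def estimate_densities(observations: pd.DataFrame, sites: pd.DataFrame,
                       fits: dict[str, DetectionFit],
                       surveys: pd.DataFrame | None = None) -> pd.DataFrame:
    """Surveys x species density table.

    One row per site x survey round, columns :data:`META_COLUMNS` followed by
    one density column per species: ``D = 1e4 * n / (2 * L * ESW)`` in
    individuals per hectare; a species absent from a survey gets 0.

    ``surveys`` is the full survey schedule (META_COLUMNS frame).  When given,
    surveys with no detections at all appear as all-zero rows — required for
    unbiased site-level means.  When omitted only surveys present in the
    observations are returned.

    All observation rows must be species-level (apportion first) and every
    observed species must have a fit.
    """
    if not observations["species_level"].all():
        raise ValueError("observations contain unapportioned higher-taxon rows")
    species = sorted(observations["taxon_code"].unique())
    missing = [s for s in species if s not in fits]
    if missing:
        raise KeyError(f"no detection fit for species {missing[:5]}")

    lengths = dict(zip(sites["site_id"], sites["transect_length_m"]))
    unknown_sites = set(observations["site_id"]) - set(lengths)
    if unknown_sites:
        raise KeyError(f"observations reference unknown sites {sorted(unknown_sites)[:5]}")

    counts = (observations
              .groupby(["site_id", "survey_round", "year", "day_of_year",
                        "taxon_code"])["count"].sum()
              .unstack("taxon_code", fill_value=0.0))
    counts = counts.reindex(columns=species, fill_value=0.0)

    table = counts.reset_index()
    if surveys is not None:
        schedule = surveys[META_COLUMNS].drop_duplicates()
        table = schedule.merge(table, on=META_COLUMNS, how="left")
        table[species] = table[species].fillna(0.0)
    L = table["site_id"].map(lengths).to_numpy(dtype=float)
    for sp in species:
        esw = fits[sp].esw
        table[sp] = 1e4 * table[sp].to_numpy() / (2.0 * L * esw)
    return (table[META_COLUMNS + species]
            .sort_values(["site_id", "survey_round"])
            .reset_index(drop=True))
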