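"""Community metrics: richness, density, conservation value, rarefaction.

Per-survey responses are the ones the downstream gradient analysis consumes:

* richness — number of species with nonzero density on a survey;
* total density — sum of species densities (individuals ha^-1);
* CVI — the Conservation Value Index, a density-weighted sum of reversed
  NatureServe imperilment ranks over species ranked vulnerable or worse.

NatureServe global ranks run G1 (critically imperiled) to G5 (secure); the
scale is reversed (r = 6 - numeric rank) so larger r means more imperiled,
range ranks ("G3G4") take the midpoint, and infraspecific T ranks override
the species-level G rank (the subspecies is what flies at the site).  Only
species with reversed rank greater than 2 — vulnerable, imperiled, or
critically imperiled — contribute:

    CVI = sum_{s: r_s > 2} r_s * D_s      (per survey, per site)

Site-level richness uses the Abundance-based Coverage Estimator (ACE), which
corrects observed richness upward using the frequencies of rare species, and
species accumulation curves support habitat comparisons of richness at a
common number of individuals and of sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import RANK_PATTERN
from .detection import META_COLUMNS
from .inference import benjamini_hochberg

__all__ = [
    "reversed_rank",
    "conservation_value_index",
    "ace_richness",
    "AccumulationCurve",
    "accumulation_curve",
    "compare_richness_at_effort",
    "compare_curves_pairwise",
    "under_canopy_summary",
    "idw_site_average",
    "survey_metrics",
    "site_metrics",
]


def reversed_rank(rank_raw: str) -> float:
    """Reversed numeric NatureServe rank in [1, 5].

    "G5" -> 1 (secure) ... "G1" -> 5 (critically imperiled); "GjGk" -> the
    midpoint; "GkTm" -> 6 - m (the infraspecific rank governs).
    """
    m = RANK_PATTERN.match(rank_raw)
    if m is None:
        raise ValueError(f"unparsable NatureServe rank {rank_raw!r}")
    g1, g2, t = m.groups()
    if t is not None:
        numeric = float(t)
    elif g2 is not None:
        numeric = (float(g1) + float(g2)) / 2.0
    else:
        numeric = float(g1)
    return 6.0 - numeric


def conservation_value_index(densities: pd.Series | dict,
                             ranks: pd.Series | dict) -> float:
    """CVI for one survey: sum of r_s * D_s over species with r_s > 2."""
    dens = pd.Series(densities, dtype=float)
    rk = pd.Series(ranks, dtype=float)
    missing = dens.index.difference(rk.index)
    if len(missing):
        raise KeyError(f"species missing a reversed rank: {list(missing)[:5]}")
    rk = rk.reindex(dens.index)
    keep = rk > 2
    return float((rk[keep] * dens[keep]).sum())


def ace_richness(abundances, rare_cutoff: int = 10) -> float:
    """Abundance-based Coverage Estimator of species richness.

    With rare species those of abundance <= ``rare_cutoff``:

        S_ACE = S_abund + S_rare / C + (F1 / C) * gamma^2
        C = 1 - F1 / N_rare
        gamma^2 = max[(S_rare / C) * sum_i i(i-1) F_i / (N_rare (N_rare - 1)) - 1, 0]

    where F_i is the number of rare species with abundance exactly i.  Raises
    when sample coverage C is zero (every rare individual a singleton).
    """
    a = np.asarray([x for x in abundances if x > 0], dtype=float)
    if a.size == 0:
        return 0.0
    if not np.allclose(a, np.round(a)):
        raise ValueError("ACE requires integer abundances")
    a = np.round(a).astype(int)
    rare = a[a <= rare_cutoff]
    s_abund = int(np.sum(a > rare_cutoff))
    if rare.size == 0:
        return float(s_abund)
    s_rare = rare.size
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c = 1.0 - f1 / n_rare
    if c == 0.0:
        raise ZeroDivisionError(
            "ACE undefined: all rare individuals are singletons (coverage 0)")
    fsum = sum(i * (i - 1) * int(np.sum(rare == i))
               for i in range(1, rare_cutoff + 1))
    gamma2 = 0.0
    if n_rare > 1:
        gamma2 = max((s_rare / c) * fsum / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    return float(s_abund + s_rare / c + (f1 / c) * gamma2)


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean/variance of accumulated species as a function of sampling effort."""

    mode: str                 # "individuals" or "sites"
    effort: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    n_randomizations: int

    def at(self, effort: float) -> tuple[float, float]:
        """(mean, variance) at an effort value on the grid."""
        idx = np.nonzero(self.effort == effort)[0]
        if idx.size == 0:
            raise ValueError(f"effort {effort} not on the curve grid "
                             f"(max {self.effort.max()})")
        return float(self.mean[idx[0]]), float(self.variance[idx[0]])


_EXHAUSTIVE_SITE_LIMIT = 7  # 7! = 5040 orderings; enumerate exactly below this


def accumulation_curve(matrix: pd.DataFrame | np.ndarray, mode: str,
                       n_randomizations: int = 200, seed: int | None = None,
                       effort_grid=None) -> AccumulationCurve:
    """Species accumulation by random site orderings or individual draws.

    ``matrix`` is sites x species (abundances; incidence suffices for site
    mode).  Site mode accumulates species over random orderings of the rows —
    enumerated exhaustively when there are at most 7 sites, randomized
    otherwise.  Individuals mode draws individuals without replacement and
    records species accumulation on ``effort_grid`` (default: every integer up
    to the total count, capped for readability at 1000 grid points).
    """
    m = np.asarray(matrix, dtype=float)
    if mode not in ("sites", "individuals"):
        raise ValueError(f"mode must be 'sites' or 'individuals', got {mode!r}")
    rng = np.random.default_rng(seed)

    if mode == "sites":
        n_sites = m.shape[0]
        effort = np.arange(1, n_sites + 1)
        if effort_grid is not None:
            bad = [e for e in np.atleast_1d(effort_grid) if e > n_sites]
            if bad:
                raise ValueError(f"effort beyond available sites: {bad}")
        if n_sites <= _EXHAUSTIVE_SITE_LIMIT:
            orders = list(itertools.permutations(range(n_sites)))
        else:
            orders = [rng.permutation(n_sites) for _ in range(n_randomizations)]
        richness = np.empty((len(orders), n_sites))
        present = m > 0
        for r, order in enumerate(orders):
            seen = np.zeros(m.shape[1], dtype=bool)
            for k, i in enumerate(order):
                seen |= present[i]
                richness[r, k] = seen.sum()
        curve_effort = effort
    else:
        if not np.allclose(m, np.round(m)):
            raise ValueError("individuals mode requires integer abundances")
        totals = np.round(m.sum(axis=0)).astype(int)  # per species
        n_total = int(totals.sum())
        if n_total == 0:
            raise ValueError("no individuals in matrix")
        if effort_grid is None:
            step = max(1, n_total // 1000)
            curve_effort = np.arange(step, n_total + 1, step)
            if curve_effort[-1] != n_total:
                curve_effort = np.append(curve_effort, n_total)
        else:
            curve_effort = np.sort(np.atleast_1d(effort_grid)).astype(int)
            if curve_effort[-1] > n_total:
                raise ValueError(
                    f"effort {curve_effort[-1]} beyond total count {n_total}")
        labels = np.repeat(np.arange(m.shape[1]), totals)
        richness = np.empty((n_randomizations, curve_effort.size))
        for r in range(n_randomizations):
            perm = rng.permutation(labels)
            # first occurrence position of each species in this ordering
            first = np.full(m.shape[1], n_total + 1)
            seen_at = {}
            for pos, sp in enumerate(perm):
                if sp not in seen_at:
                    seen_at[sp] = pos + 1
            for sp, pos in seen_at.items():
                first[sp] = pos
            richness[r] = np.searchsorted(np.sort(first), curve_effort,
                                          side="right")

    mean = richness.mean(axis=0)
    var = richness.var(axis=0, ddof=1) if richness.shape[0] > 1 else \
        np.zeros(richness.shape[1])
    return AccumulationCurve(mode=mode, effort=np.asarray(curve_effort),
                             mean=mean, variance=var,
                             n_randomizations=len(richness))


def compare_richness_at_effort(curve_a: AccumulationCurve,
                               curve_b: AccumulationCurve,
                               effort: float) -> dict:
    """Two-sided z-test of accumulated richness at a common effort.

    z = (mean_A - mean_B) / sqrt(var_A + var_B) with normal reference.
    """
    ma, va = curve_a.at(effort)
    mb, vb = curve_b.at(effort)
    pooled = va + vb
    if pooled <= 0:
        raise ZeroDivisionError("zero combined variance at this effort")
    z = (ma - mb) / math.sqrt(pooled)
    p = 2.0 * norm.sf(abs(z))
    return {"z": z, "p": p}


def compare_curves_pairwise(curves: dict[str, AccumulationCurve],
                            effort: float) -> pd.DataFrame:
    """All pairwise z-tests among named curves, Benjamini-Hochberg adjusted."""
    rows = []
    for a, b in itertools.combinations(sorted(curves), 2):
        r = compare_richness_at_effort(curves[a], curves[b], effort)
        rows.append({"group_a": a, "group_b": b, "z": r["z"], "p_raw": r["p"]})
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    return out


def under_canopy_summary(observations: pd.DataFrame, traits: pd.DataFrame,
                         min_obs: int = 20) -> pd.DataFrame:
    """Per-family percentage of observations made directly under canopy.

    ``overall_pct`` pools all of a family's observations; ``species_mean_pct``
    (with its SE) is the unweighted mean of per-species percentages over the
    species with more than ``min_obs`` observations.
    """
    obs = observations[observations["species_level"]].copy()
    fam = dict(zip(traits["species_code"], traits["family"]))
    obs["family"] = obs["taxon_code"].map(fam)

    def pct(frame):
        w = frame["count"].sum()
        return 100.0 * frame.loc[frame["under_canopy"], "count"].sum() / w

    rows = []
    for family, fobs in obs.groupby("family"):
        per_species = []
        for _, sobs in fobs.groupby("taxon_code"):
            if sobs["count"].sum() > min_obs:
                per_species.append(pct(sobs))
        per_species = np.asarray(per_species)
        rows.append({
            "family": family,
            "overall_pct": pct(fobs),
            "n_overall": fobs["count"].sum(),
            "species_mean_pct": per_species.mean() if per_species.size else np.nan,
            "species_se_pct": (per_species.std(ddof=1) / math.sqrt(per_species.size)
                               if per_species.size > 1 else np.nan),
            "n_species": per_species.size,
        })
    return pd.DataFrame(rows)


def idw_site_average(values, distances_from_center) -> float:
    """Inverse-distance-weighted average of plot values (exponent 1)."""
    v = np.asarray(values, dtype=float)
    d = np.asarray(distances_from_center, dtype=float)
    if v.shape != d.shape:
        raise ValueError("values and distances must have the same length")
    if np.any(d <= 0):
        raise ValueError("all distances must be > 0")
    w = 1.0 / d
    return float(np.sum(v * w) / np.sum(w))


# ---------------------------------------------------------------------------
# pipeline helpers over the density table
# ---------------------------------------------------------------------------

def survey_metrics(density_table: pd.DataFrame,
                   reversed_ranks: pd.Series | dict) -> pd.DataFrame:
    """Per-survey richness, total density, and CVI from a density table."""
    species = [c for c in density_table.columns if c not in META_COLUMNS]
    rk = pd.Series(reversed_ranks, dtype=float).reindex(species)
    if rk.isna().any():
        raise KeyError(
            f"species missing a reversed rank: {list(rk.index[rk.isna()])[:5]}")
    dens = density_table[species].to_numpy()
    out = density_table[META_COLUMNS].copy()
    out["richness"] = (dens > 0).sum(axis=1)
    out["total_density"] = dens.sum(axis=1)
    keep = (rk > 2).to_numpy()
    out["cvi"] = dens[:, keep] @ rk.to_numpy()[keep]
    return out


def site_metrics(density_table: pd.DataFrame,
                 observations: pd.DataFrame,
                 reversed_ranks: pd.Series | dict,
                 rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-site summaries: mean per-survey density and CVI, ACE richness.

    Means are taken across all survey rounds (zero surveys included).  ACE is
    computed from each site's whole-season species-level observation counts,
    rounded to integers.
    """
    per_survey = survey_metrics(density_table, reversed_ranks)
    agg = per_survey.groupby("site_id").agg(
        mean_density=("total_density", "mean"),
        mean_cvi=("cvi", "mean"),
        mean_richness=("richness", "mean"),
    ).reset_index()

    obs = observations[observations["species_level"]]
    ace = {}
    for site, sobs in obs.groupby("site_id"):
        counts = np.round(sobs.groupby("taxon_code")["count"].sum()).astype(int)
        ace[site] = ace_richness(counts[counts > 0], rare_cutoff)
    agg["ace_richness"] = agg["site_id"].map(ace)
    return agg
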