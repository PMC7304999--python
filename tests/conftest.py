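import numpy as np
import pandas as pd
import pytest

from canopycomm import detection, synthetic_data as synth


@pytest.fixture(scope="session")
def default_sim():
    """One full default-design simulation (25 sites x 21 rounds, 60 species)."""
    return synth.simulate_dataset(synth.default_config(1))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Apportioned observations, detection fits, and the density table."""
    obs = detection.apportion_unidentified(default_sim.observations,
                                           default_sim.species_traits)
    fits = detection.fit_detection_groups(obs, default_sim.species_traits)
    dens = detection.estimate_densities(
        obs, default_sim.sites, fits,
        surveys=default_sim.ground_truth[detection.META_COLUMNS])
    return {"observations": obs, "fits": fits, "densities": dens}


def flat_species(code="gen00_sp00", family="famA", amplitude=10.0,
                 sigma=3.0, rank="G5"):
    """A species with an essentially flat niche and season (lambda ~ A everywhere)."""
    return synth.SpeciesSimSpec(
        species_code=code, family=family, niche_optimum=50.0,
        niche_breadth=1e4, peak_density=amplitude, phenology_peak=200.0,
        phenology_sd=1e4, detection_sigma=sigma, natureserve_rank_raw=rank)


@pytest.fixture()
def toy_observations():
    """Hand-written observations: two sites, one day, Pieridae apportionment toy."""
    rows = []
    # site A, day 150: 6 identified P. rapae, 2 C. eurytheme, 4 unidentified Pieridae
    for _ in range(6):
        rows.append(("A", 1998, 150, 1, "Pieris rapae", True, 2.0, 1.0, False))
    for _ in range(2):
        rows.append(("A", 1998, 150, 1, "Colias eurytheme", True, 3.0, 1.0, False))
    for _ in range(4):
        rows.append(("A", 1998, 150, 1, "Pieridae", False, 1.0, 1.0, False))
    # site B, day 150: only unidentified Pieridae -> dropped
    rows.append(("B", 1998, 150, 1, "Pieridae", False, 1.0, 2.0, False))
    return pd.DataFrame(rows, columns=[
        "site_id", "year", "day_of_year", "survey_round", "taxon_code",
        "species_level", "distance_m", "count", "under_canopy"])


@pytest.fixture()
def toy_traits():
    return pd.DataFrame({
        "species_code": ["Pieris rapae", "Colias eurytheme"],
        "family": ["Pieridae", "Pieridae"],
        "natureserve_rank": ["G5", "G5"],
    })
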