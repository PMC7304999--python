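import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from canopycomm import detection
from canopycomm.detection import (DetectionFit, apportion_unidentified,
                                  effective_strip_width, estimate_densities,
                                  fit_halfnormal, pool_species)


def _obs(rows):
    return pd.DataFrame(rows, columns=[
        "site_id", "year", "day_of_year", "survey_round", "taxon_code",
        "species_level", "distance_m", "count", "under_canopy"])


def _simple_obs(counts: dict[str, int]):
    rows = []
    for sp, n in counts.items():
        for i in range(n):
            rows.append(("s1", 1998, 150, 1, sp, True, 1.0 + i % 3, 1.0, False))
    return _obs(rows)


def _traits(codes_families):
    return pd.DataFrame({
        "species_code": [c for c, _ in codes_families],
        "family": [f for _, f in codes_families],
        "natureserve_rank": "G5",
    })


class TestPooling:
    def test_abundant_species_stands_alone(self):
        obs = _simple_obs({"Aus bus": 100})
        traits = _traits([("Aus bus", "F1")])
        assert pool_species(obs, traits, 30) == {"Aus bus": "Aus bus"}

    def test_sparse_species_joins_congener(self):
        obs = _simple_obs({"Aus bus": 5, "Aus cus": 60})
        traits = _traits([("Aus bus", "F1"), ("Aus cus", "F1")])
        groups = pool_species(obs, traits, 30)
        assert groups["Aus bus"] == "genus:Aus"
        assert groups["Aus cus"] == "Aus cus"

    def test_falls_back_to_family_then_global(self):
        obs = _simple_obs({"Aus bus": 5, "Cus dus": 40, "Eus fus": 2})
        traits = _traits([("Aus bus", "F1"), ("Cus dus", "F1"),
                          ("Eus fus", "F2")])
        groups = pool_species(obs, traits, 30)
        assert groups["Aus bus"] == "family:F1"
        assert groups["Eus fus"] == "global"

    def test_partition_covers_every_species_once(self, default_sim):
        groups = pool_species(default_sim.observations,
                              default_sim.species_traits, 30)
        assert set(groups) == set(default_sim.species_traits["species_code"])

    def test_unknown_species_rejected(self):
        obs = _simple_obs({"Aus bus": 5})
        with pytest.raises(KeyError, match="absent from traits"):
            pool_species(obs, _traits([("Other sp", "F1")]), 30)

    def test_pooled_members_share_one_esw(self):
        # two sparse congeners share one fit, borrowed from the whole genus
        obs = _simple_obs({"Aus bus": 5, "Aus dus": 4, "Aus cus": 60})
        traits = _traits([("Aus bus", "F1"), ("Aus dus", "F1"),
                          ("Aus cus", "F1")])
        fits = detection.fit_detection_groups(obs, traits, 30)
        assert fits["Aus bus"] is fits["Aus dus"]
        assert fits["Aus bus"].esw == fits["Aus dus"].esw
        # the pooled fit uses all congeners' distances, the abundant
        # congener keeps its own fit from its own 60 detections
        assert fits["Aus bus"].n_detections == 69
        assert fits["Aus cus"].n_detections == 60


class TestHalfNormalFit:
    def test_closed_form_untruncated_mle(self):
        fit = fit_halfnormal([1.0, 2.0, 2.0, 3.0])
        assert fit.sigma == pytest.approx(math.sqrt(4.5), rel=1e-12)

    def test_closed_form_matches_numeric_maximization(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        sumsq = (x ** 2).sum()

        def nll(s):
            esw = s * math.sqrt(math.pi / 2)
            return len(x) * math.log(esw) + sumsq / (2 * s * s)

        res = minimize_scalar(nll, bounds=(0.01, 100), method="bounded",
                              options={"xatol": 1e-12})
        assert fit_halfnormal(x).sigma == pytest.approx(res.x, rel=1e-6)

    def test_all_zero_distances_degenerate(self):
        with pytest.raises(detection.DegenerateFitError):
            fit_halfnormal([0.0, 0.0, 0.0])

    def test_recovers_sigma_from_simulated_distances(self):
        rng = np.random.default_rng(11)
        x = np.abs(rng.normal(0, 3.0, size=500))
        assert fit_halfnormal(x).sigma == pytest.approx(3.0, rel=0.1)

    def test_truncated_fit_near_untruncated_for_wide_truncation(self):
        rng = np.random.default_rng(3)
        x = np.abs(rng.normal(0, 2.0, size=400))
        x = x[x < 15.0]
        free = fit_halfnormal(x)
        trunc = fit_halfnormal(x, truncation=15.0)
        assert trunc.sigma == pytest.approx(free.sigma, rel=1e-3)


class TestEffectiveStripWidth:
    def test_perfect_detection_to_truncation(self):
        fit = DetectionFit("g", (), sigma=1e6, truncation=5.0, esw=0.0,
                           n_detections=10, log_likelihood=0.0)
        assert effective_strip_width(fit) == pytest.approx(5.0, rel=1e-6)

    def test_untruncated_closed_form(self):
        fit = DetectionFit("g", (), sigma=2.1213, truncation=math.inf, esw=0.0,
                           n_detections=10, log_likelihood=0.0)
        assert effective_strip_width(fit) == pytest.approx(2.659, abs=1e-3)

    @settings(max_examples=40, derandomize=True)
    @given(st.floats(0.5, 10), st.floats(0.5, 10), st.floats(1, 50))
    def test_monotone_in_sigma_and_truncation(self, s1, s2, w):
        lo, hi = sorted((s1, s2))
        f = lambda s, t: effective_strip_width(
            DetectionFit("g", (), sigma=s, truncation=t, esw=0.0,
                         n_detections=1, log_likelihood=0.0))
        assert f(lo, w) <= f(hi, w) + 1e-12
        assert f(s1, w) <= f(s1, 2 * w) + 1e-12
        assert f(s1, w) <= s1 * math.sqrt(math.pi / 2) + 1e-12


class TestApportionment:
    def test_proportional_split(self, toy_observations, toy_traits):
        out = apportion_unidentified(toy_observations, toy_traits)
        totals = out.groupby("taxon_code")["count"].sum()
        # 4 unidentified split 6:2 over the identified counts -> +3 and +1
        assert totals["Pieris rapae"] == pytest.approx(9.0)
        assert totals["Colias eurytheme"] == pytest.approx(3.0)

    def test_no_candidates_dropped_and_conserved(self, toy_observations,
                                                 toy_traits, caplog):
        import logging
        with caplog.at_level(logging.INFO, logger="canopycomm.detection"):
            out = apportion_unidentified(toy_observations, toy_traits)
        # site B had no identified Pieridae that day: its 2 individuals drop
        before = toy_observations["count"].sum()
        dropped = 2.0
        assert out["count"].sum() == pytest.approx(before - dropped)
        assert "no identified candidates" in caplog.text
        assert out["species_level"].all()

    def test_unknown_taxon_code_rejected(self, toy_traits):
        obs = _obs([("A", 1998, 150, 1, "Nymphalidae", False, 1.0, 1.0, False)])
        with pytest.raises(KeyError, match="no candidate species"):
            apportion_unidentified(obs, toy_traits)


class TestDensities:
    def _fit(self, esw):
        sigma = esw / math.sqrt(math.pi / 2)
        return DetectionFit("g", (), sigma=sigma, truncation=math.inf,
                            esw=esw, n_detections=50, log_likelihood=0.0)

    def _sites(self):
        return pd.DataFrame({"site_id": ["s1"], "x_m": [0.0], "y_m": [0.0],
                             "transect_length_m": [500.0],
                             "canopy_cover_pct": [50.0], "habitat": ["savanna"],
                             "fire2": 0, "fire15": 0, "veg_short": 0,
                             "veg_tall": 0, "litter": 0, "habitat_diversity": 1,
                             "developed_pct": 0, "agriculture_pct": 0})

    def test_hand_computed_density(self):
        obs = _obs([("s1", 1998, 150, 1, "sp", True, 1.0, 10.0, False)])
        table = estimate_densities(obs, self._sites(), {"sp": self._fit(2.0)})
        # D = 1e4 * 10 / (2 * 500 * 2) = 50 per ha
        assert table.loc[0, "sp"] == pytest.approx(50.0)

    def test_absent_species_zero(self):
        obs = _obs([("s1", 1998, 150, 1, "sp", True, 1.0, 10.0, False)])
        surveys = pd.DataFrame({"site_id": ["s1", "s1"], "survey_round": [1, 2],
                                "year": [1998, 1998], "day_of_year": [150, 160]})
        table = estimate_densities(obs, self._sites(), {"sp": self._fit(2.0)},
                                   surveys=surveys)
        assert len(table) == 2
        assert table.loc[table["survey_round"] == 2, "sp"].iloc[0] == 0.0

    def test_doubling_esw_halves_density(self):
        obs = _obs([("s1", 1998, 150, 1, "sp", True, 1.0, 10.0, False)])
        d1 = estimate_densities(obs, self._sites(), {"sp": self._fit(2.0)})
        d2 = estimate_densities(obs, self._sites(), {"sp": self._fit(4.0)})
        assert d1.loc[0, "sp"] == pytest.approx(2 * d2.loc[0, "sp"])

    def test_unapportioned_rows_rejected(self):
        obs = _obs([("s1", 1998, 150, 1, "Pieridae", False, 1.0, 1.0, False)])
        with pytest.raises(ValueError, match="unapportioned"):
            estimate_densities(obs, self._sites(), {})

    def test_missing_fit_rejected(self):
        obs = _obs([("s1", 1998, 150, 1, "sp", True, 1.0, 1.0, False)])
        with pytest.raises(KeyError, match="no detection fit"):
            estimate_densities(obs, self._sites(), {})
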