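import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from canopycomm import community
from canopycomm.community import (accumulation_curve, ace_richness,
                                  compare_curves_pairwise,
                                  compare_richness_at_effort,
                                  conservation_value_index, idw_site_average,
                                  reversed_rank, under_canopy_summary)
from canopycomm.core import load_table2_fixture


class TestReversedRank:
    @pytest.mark.parametrize("raw,expected", [
        ("G5", 1.0), ("G1", 5.0),          # plain ranks, reversed
        ("G3G4", 2.5), ("G4G5", 1.5),      # range ranks -> midpoint
        ("G5T2", 4.0), ("G4T1", 5.0),      # T rank overrides G
    ])
    def test_grammar_cases(self, raw, expected):
        assert reversed_rank(raw) == expected

    def test_unparsable_rejected(self):
        with pytest.raises(ValueError, match="unparsable"):
            reversed_rank("GX")

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(1, 5), st.integers(1, 5))
    def test_always_in_unit_interval(self, g, t):
        assert 1.0 <= reversed_rank(f"G{g}") <= 5.0
        assert 1.0 <= reversed_rank(f"G{g}T{t}") <= 5.0


#: NatureServe ranks of the 61-species community as published; every species
#: not listed is secure (G5).
PUBLISHED_NONSECURE_RANKS = {
    "Celastrina ladon": "G4G5",
    "Atrytonopsis hianna": "G4G5",
    "Polites origenes": "G4G5",
    "Papilio troilus": "G4",
    "Satyrodes appalachia": "G4",
    "Problema byssus": "G3G4",
    "Erynnis martialis": "G3",
    "Lycaeides melissa samuelis": "G5T2",
    "Danaus plexippus": "G4T1",
}


class TestCVI:
    def test_all_secure_is_zero(self):
        d = {"a": 5.0, "b": 2.0}
        r = {"a": 1.0, "b": 1.0}
        assert conservation_value_index(d, r) == 0.0

    def test_hand_computed_toy(self):
        d = {"a": 2.0, "b": 1.0, "c": 10.0}
        r = {"a": 3.0, "b": 5.0, "c": 2.0}
        # r=2 is excluded (strictly greater than 2 required): 3*2 + 5*1 = 11
        assert conservation_value_index(d, r) == pytest.approx(11.0)

    def test_published_ranks_select_four_imperiled_taxa(self):
        t2 = load_table2_fixture()
        ranks = {sp: reversed_rank(PUBLISHED_NONSECURE_RANKS.get(sp, "G5"))
                 for sp in t2["species_name"]}
        included = sorted(sp for sp, r in ranks.items() if r > 2)
        assert included == sorted([
            "Problema byssus", "Erynnis martialis",
            "Lycaeides melissa samuelis", "Danaus plexippus"])

    def test_missing_rank_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            conservation_value_index({"a": 1.0}, {})

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(0.1, 50), st.floats(0, 10), st.floats(0, 10))
    def test_linear_in_densities(self, alpha, d1, d2):
        dens = {"a": d1, "b": d2}
        ranks = {"a": 3.0, "b": 4.5}
        scaled = {k: alpha * v for k, v in dens.items()}
        assert conservation_value_index(scaled, ranks) == pytest.approx(
            alpha * conservation_value_index(dens, ranks))


class TestACE:
    def test_no_rare_species_returns_observed(self):
        assert ace_richness([15, 20, 100]) == 3.0

    def test_hand_computed_example(self):
        # S_abund=2, S_rare=4, N_rare=7, F1=2, C=5/7,
        # gamma^2 = max(5.6 * 8/42 - 1, 0) = 0.0667 -> 7.7867
        assert ace_richness([1, 1, 2, 3, 12, 20]) == pytest.approx(7.7867, abs=1e-3)

    def test_adding_abundant_species_adds_one(self):
        base = ace_richness([1, 1, 2, 3, 12, 20])
        assert ace_richness([1, 1, 2, 3, 12, 20, 500]) == pytest.approx(base + 1)

    def test_ace_at_least_observed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(1, 30, size=rng.integers(3, 15))
            try:
                est = ace_richness(a)
            except ZeroDivisionError:
                continue
            assert est >= len(a) - 1e-9

    def test_all_singletons_undefined(self):
        with pytest.raises(ZeroDivisionError, match="coverage"):
            ace_richness([1, 1, 1])


class TestAccumulation:
    def test_single_site_single_point(self):
        m = np.array([[3, 0, 1]])
        curve = accumulation_curve(m, "sites")
        assert curve.effort.tolist() == [1]
        assert curve.mean[0] == 2.0

    def test_full_effort_reaches_total_richness(self):
        rng = np.random.default_rng(2)
        m = rng.poisson(1.0, size=(6, 12))
        total = int((m.sum(axis=0) > 0).sum())
        curve = accumulation_curve(m, "sites")
        assert curve.mean[-1] == total
        assert curve.variance[-1] == pytest.approx(0.0, abs=1e-12)

    def test_three_site_toy_matches_exhaustive_oracle(self):
        m = np.array([[1, 1, 0, 0],
                      [0, 1, 1, 0],
                      [0, 0, 1, 1]])
        # brute force over all 3! orderings, written independently
        expected = np.zeros(3)
        for order in itertools.permutations(range(3)):
            seen = set()
            for k, i in enumerate(order):
                seen |= set(np.nonzero(m[i])[0])
                expected[k] += len(seen)
        expected /= 6
        curve = accumulation_curve(m, "sites")
        np.testing.assert_allclose(curve.mean, expected)

    def test_individuals_mode_matches_hypergeometric_oracle(self):
        m = np.array([[5, 3, 1, 0], [2, 0, 4, 1]])
        totals = m.sum(axis=0)
        n = int(totals.sum())
        curve = accumulation_curve(m, "individuals", n_randomizations=3000,
                                   seed=5, effort_grid=[4, 8, 12])
        for effort, got in zip(curve.effort, curve.mean):
            exact = sum(1 - math.comb(n - t, effort) / math.comb(n, effort)
                        for t in totals)
            assert got == pytest.approx(exact, abs=0.08)

    def test_mean_nondecreasing_in_effort(self):
        rng = np.random.default_rng(9)
        m = rng.poisson(0.7, size=(10, 25))
        for mode in ("sites", "individuals"):
            curve = accumulation_curve(m, mode, n_randomizations=50, seed=1)
            assert (np.diff(curve.mean) >= -1e-9).all()

    def test_effort_beyond_total_rejected(self):
        with pytest.raises(ValueError, match="effort"):
            accumulation_curve(np.array([[2, 1]]), "individuals",
                               effort_grid=[10], seed=0)


class TestRichnessComparison:
    def _curve(self, mean, var, effort=10):
        return community.AccumulationCurve(
            mode="individuals", effort=np.array([effort]),
            mean=np.array([mean]), variance=np.array([var]),
            n_randomizations=100)

    def test_identical_curves_no_difference(self):
        a = self._curve(10.0, 1.0)
        r = compare_richness_at_effort(a, self._curve(10.0, 1.0), 10)
        assert r["z"] == 0.0 and r["p"] == pytest.approx(1.0)

    def test_hand_computed_z(self):
        r = compare_richness_at_effort(self._curve(10.0, 1.0),
                                       self._curve(13.0, 1.25), 10)
        assert r["z"] == pytest.approx(-2.0)
        assert r["p"] == pytest.approx(0.0455, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compare_richness_at_effort(self._curve(10, 0.0),
                                       self._curve(11, 0.0), 10)

    def test_pairwise_battery_adjusts_upward(self):
        curves = {"open": self._curve(10, 1.0), "savanna": self._curve(13, 1.25),
                  "forest": self._curve(9, 0.8)}
        table = compare_curves_pairwise(curves, 10)
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()
        assert len(table) == 3


class TestUnderCanopy:
    def _obs(self, rows):
        return pd.DataFrame(rows, columns=[
            "site_id", "year", "day_of_year", "survey_round", "taxon_code",
            "species_level", "distance_m", "count", "under_canopy"])

    def _traits(self):
        return pd.DataFrame({
            "species_code": ["a_x", "a_y", "a_z"],
            "family": ["famA"] * 3, "natureserve_rank": "G5"})

    def test_all_under_canopy_is_100(self):
        rows = [("s", 1998, 1, 1, "a_x", True, 1.0, 1.0, True)] * 25
        out = under_canopy_summary(self._obs(rows), self._traits())
        assert out.loc[0, "overall_pct"] == 100.0

    def test_species_mean_excludes_sparse_species(self):
        rows = []
        # species x: 30 obs, 40% under canopy
        rows += [("s", 1998, 1, 1, "a_x", True, 1.0, 1.0, i < 12)
                 for i in range(30)]
        # species y: 25 obs, 20% under canopy
        rows += [("s", 1998, 1, 1, "a_y", True, 1.0, 1.0, i < 5)
                 for i in range(25)]
        # species z: only 10 obs -> excluded from the species mean
        rows += [("s", 1998, 1, 1, "a_z", True, 1.0, 1.0, True)
                 for _ in range(10)]
        out = under_canopy_summary(self._obs(rows), self._traits(), min_obs=20)
        assert out.loc[0, "species_mean_pct"] == pytest.approx(30.0)
        assert out.loc[0, "n_species"] == 2
        # the pooled overall percentage still counts every record
        assert out.loc[0, "overall_pct"] == pytest.approx(
            100 * (12 + 5 + 10) / 65)


class TestIDW:
    def test_equal_distances_arithmetic_mean(self):
        assert idw_site_average([2.0, 4.0, 9.0], [3.0, 3.0, 3.0]) == \
            pytest.approx(5.0)

    def test_single_plot_returns_value(self):
        assert idw_site_average([7.5], [12.0]) == 7.5

    def test_hand_computed(self):
        assert idw_site_average([0.0, 10.0], [1.0, 2.0]) == \
            pytest.approx(10 * 0.5 / 1.5)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            idw_site_average([1.0], [0.0])


class TestPipelineMetrics:
    def test_richness_counts_nonzero_density_cells(self, default_pipeline,
                                                   default_sim):
        from canopycomm.detection import META_COLUMNS
        dens = default_pipeline["densities"]
        ranks = pd.Series(
            [reversed_rank(r) for r in default_sim.species_traits["natureserve_rank"]],
            index=default_sim.species_traits["species_code"])
        per_survey = community.survey_metrics(dens, ranks)
        species = [c for c in dens.columns if c not in META_COLUMNS]
        expected = (dens[species].to_numpy() > 0).sum(axis=1)
        np.testing.assert_array_equal(per_survey["richness"].to_numpy(), expected)
        assert (per_survey["cvi"] >= 0).all()

    def test_site_metrics_ace_at_least_mean_richness(self, default_pipeline,
                                                     default_sim):
        ranks = pd.Series(
            [reversed_rank(r) for r in default_sim.species_traits["natureserve_rank"]],
            index=default_sim.species_traits["species_code"])
        site = community.site_metrics(default_pipeline["densities"],
                                      default_pipeline["observations"], ranks)
        assert len(site) == 25
        assert (site["ace_richness"] >= site["mean_richness"]).all()
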