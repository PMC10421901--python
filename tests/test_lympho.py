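"""Lymphocyte densities, relative proportions ρ, α and centre binarisation."""

import numpy as np
import pandas as pd
import pytest

import ctm
from ctm.lympho import (
    HarmonisationConfig,
    centre_binarise,
    cohort_median_rho,
    ctm_alpha,
    density_per_texture,
    harmonisation_report,
    lympho_profile,
    relative_proportions,
)
from ctm.tilemap import LymphocyteMap, TileMap

from conftest import random_tilemap


def _simple_maps():
    grid = np.array(
        [["cancer", "cancer", "cancer"],
         ["stroma", "stroma", "empty"],
         ["normal", "blood", "other"]],
        dtype=object,
    )
    scores = np.array(
        [[0.2, 0.4, 0.6],
         [0.1, 0.3, np.nan],
         [0.5, 0.25, 0.05]]
    )
    return TileMap.from_labels("S", grid), LymphocyteMap("S", scores)


class TestDensity:
    def test_mean_per_texture(self):
        tmap, lmap = _simple_maps()
        dens = density_per_texture(tmap, lmap)
        assert dens["cancer"] == pytest.approx(0.4)
        assert dens["stroma"] == pytest.approx(0.2)
        assert dens["normal"] == pytest.approx(0.5)

    def test_absent_texture_is_undefined(self):
        tmap = TileMap.from_labels("S", [["cancer", "cancer"]])
        lmap = LymphocyteMap("S", np.array([[0.1, 0.3]]))
        dens = density_per_texture(tmap, lmap)
        assert np.isnan(dens["normal"])
        rho = relative_proportions(dens)
        assert rho["normal"] == 0.0 and rho["cancer"] == 100.0

    def test_saturated_scores(self):
        tmap, lmap = _simple_maps()
        ones = LymphocyteMap("S", np.where(np.isnan(lmap.grid), np.nan, 1.0))
        dens = density_per_texture(tmap, ones)
        assert all(d == pytest.approx(1.0) for d in dens.values())

    def test_shape_mismatch_rejected(self):
        tmap, _ = _simple_maps()
        with pytest.raises(ValueError, match="shape mismatch"):
            density_per_texture(tmap, LymphocyteMap("S", np.zeros((2, 2))))


class TestRho:
    def test_densities_summing_to_one_pass_through(self):
        dens = {"blood": 0.10, "cancer": 0.30, "normal": 0.40,
                "stroma": 0.15, "other": 0.05}
        assert relative_proportions(dens) == pytest.approx(
            {"blood": 10, "cancer": 30, "normal": 40, "stroma": 15, "other": 5}
        )

    def test_equal_densities_give_uniform_rho(self):
        dens = dict.fromkeys(("blood", "cancer", "normal", "stroma", "other"), 0.2)
        assert all(v == pytest.approx(20.0)
                   for v in relative_proportions(dens).values())

    def test_renormalisation_over_defined_subset(self):
        dens = {"cancer": 0.3, "stroma": 0.1, "blood": np.nan,
                "normal": np.nan, "other": np.nan}
        rho = relative_proportions(dens)
        assert rho["cancer"] == pytest.approx(75.0)
        assert rho["stroma"] == pytest.approx(25.0)

    def test_all_zero_densities_flagged_uniform(self):
        dens = {"cancer": 0.0, "stroma": 0.0}
        with pytest.warns(UserWarning, match="zero"):
            rho = relative_proportions(dens)
        assert rho == pytest.approx({"cancer": 50.0, "stroma": 50.0})


class TestAlpha:
    def test_uniform_rho_any_areas(self):
        rho = dict.fromkeys(("blood", "cancer", "normal", "stroma", "other"), 20.0)
        areas = {"blood": 3, "cancer": 97, "normal": 11, "stroma": 2, "other": 40}
        assert ctm_alpha(rho, areas) == pytest.approx(20.0)

    def test_hand_evaluated_weighted_mean(self):
        rho = {"blood": 10, "cancer": 40, "normal": 30, "stroma": 15, "other": 5}
        areas = {"blood": 10, "cancer": 50, "normal": 20, "stroma": 15, "other": 5}
        assert ctm_alpha(rho, areas) == pytest.approx(29.5)

    def test_single_texture_limit(self):
        assert ctm_alpha({"cancer": 37.0}, {"cancer": 123}) == pytest.approx(37.0)

    def test_zero_area_is_an_error(self):
        with pytest.raises(ValueError, match="zero total tissue area"):
            ctm_alpha({"cancer": 10.0}, {"cancer": 0})

    def test_alpha_scale_free_in_area_units(self, rng):
        rho = {"blood": 5, "cancer": 45, "normal": 25, "stroma": 20, "other": 5}
        areas = {t: int(n) for t, n in zip(rho, rng.integers(1, 50, 5))}
        px = {t: n * 256 * 256 for t, n in areas.items()}
        assert ctm_alpha(rho, areas) == pytest.approx(ctm_alpha(rho, px))

    def test_alpha_within_rho_convex_hull(self, rng):
        for i in range(40):
            tmap, lmap = random_tilemap(rng, 10, 10, f"S{i}")
            prof = lympho_profile(tmap, lmap)
            defined = [v for t, v in prof.rho.items()
                       if not np.isnan(prof.density[t])]
            assert sum(defined) == pytest.approx(100.0, abs=1e-6)
            if not np.isnan(prof.alpha):
                assert min(defined) - 1e-9 <= prof.alpha <= max(defined) + 1e-9


class TestCentreBinarise:
    def _cohort(self, ids, centre="X"):
        return pd.DataFrame(
            {"sample_id": ids, "centre_id": centre, "microns_per_px": 0.25}
        )

    def test_strict_median_rule_21_samples(self):
        ids = [f"s{i}" for i in range(1, 22)]
        values = pd.Series(range(1, 22), index=ids, dtype=float)
        cls = centre_binarise(values, self._cohort(ids))
        assert cls["s21"] == "High"
        assert cls["s1"] == "Low"
        assert cls["s11"] == "Low"  # the median itself: ties go Low
        assert (cls == "High").sum() <= int(np.ceil(21 / 2))

    def test_centre_of_twenty_is_all_na(self):
        ids = [f"s{i}" for i in range(20)]
        cls = centre_binarise(pd.Series(range(20), index=ids, dtype=float),
                              self._cohort(ids))
        assert (cls == "NA").all()

    def test_identical_values_all_low(self):
        ids = [f"s{i}" for i in range(25)]
        cls = centre_binarise(pd.Series(1.0, index=ids), self._cohort(ids))
        assert (cls == "Low").all()

    def test_excluded_centre_is_na(self):
        ids = [f"s{i}" for i in range(25)]
        cfg = HarmonisationConfig(excluded_centres=("X",))
        cls = centre_binarise(pd.Series(range(25), index=ids, dtype=float),
                              self._cohort(ids), cfg)
        assert (cls == "NA").all()


class TestHarmonisation:
    def _cohort_values(self, seed, centres):
        cfg = ctm.SyntheticCohortConfig(seed=seed, centres=centres,
                                        grid_shape=(40, 40))
        maps, cohort, _ = ctm.generate_cohort(cfg)
        raw, alpha = {}, {}
        for sid, (t, l) in maps.items():
            lp = lympho_profile(t, l)
            raw[sid] = lp.total_density
            alpha[sid] = lp.alpha
        return pd.Series(raw), pd.Series(alpha), cohort

    def test_biased_centres_variance_shrinks(self):
        centres = [
            ctm.CentreConfig("A", n_samples=12, p_nplus=0.9, stain_bias=0.7),
            ctm.CentreConfig("B", n_samples=12, p_nplus=0.0, stain_bias=1.4),
        ]
        raw, alpha, cohort = self._cohort_values(11, centres)
        rep = harmonisation_report(raw, alpha, cohort)
        assert rep["variance_ratio_alpha_raw"] < 1

    def test_identical_centres_no_bias_to_remove(self):
        centres = [
            ctm.CentreConfig("A", n_samples=15, p_nplus=0.5, stain_bias=1.0),
            ctm.CentreConfig("B", n_samples=15, p_nplus=0.5, stain_bias=1.0),
        ]
        raw, alpha, cohort = self._cohort_values(12, centres)
        rep = harmonisation_report(raw, alpha, cohort)
        # no injected bias: neither measure should show a large dispersion
        assert rep["raw"]["kruskal_p"] > 0.01
        assert rep["alpha"]["kruskal_p"] > 0.01

    def test_single_centre_degenerate(self):
        centres = [ctm.CentreConfig("A", n_samples=5, p_nplus=0.5)]
        raw, alpha, cohort = self._cohort_values(13, centres)
        with pytest.warns(UserWarning, match="fewer than two centres"):
            rep = harmonisation_report(raw, alpha, cohort)
        assert rep["degenerate"]

    def test_cohort_median_rho_sums_to_100(self, rng):
        dens = []
        for i in range(10):
            tmap, lmap = random_tilemap(rng, 8, 8, f"S{i}")
            dens.append(density_per_texture(tmap, lmap))
        rho = cohort_median_rho(dens)
        assert sum(rho.values()) == pytest.approx(100.0)
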