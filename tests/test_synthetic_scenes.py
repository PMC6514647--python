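"""Synthetic season generator: determinism, study structure, forward-inverse
consistency."""

import numpy as np
import pytest

from metricet import radiometry, synthetic_scenes as syn


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = syn.SeasonConfig(seed=9)
        s1, t1 = syn.generate_scene(cfg, 202)
        s2, t2 = syn.generate_scene(cfg, 202)
        assert np.array_equal(s1.red, s2.red)
        assert np.array_equal(s1.thermal_radiance, s2.thermal_radiance)
        assert np.array_equal(t1.eta, t2.eta)

    def test_different_seed_differs(self):
        a, _ = syn.generate_scene(syn.SeasonConfig(seed=1), 202)
        b, _ = syn.generate_scene(syn.SeasonConfig(seed=2), 202)
        assert not np.array_equal(a.red, b.red)

    def test_weather_deterministic(self):
        cfg = syn.SeasonConfig(seed=4)
        assert syn.generate_weather(cfg).equals(syn.generate_weather(cfg))


class TestStudyStructure:
    def test_overpass_winds(self):
        cfg = syn.SeasonConfig(seed=0)
        weather = syn.generate_weather(cfg)
        by_doy = weather.set_index("doy")
        assert by_doy.loc[194, "u"] == pytest.approx(5.9)
        for doy in (178, 202, 218, 234, 258):
            assert by_doy.loc[doy, "u"] == pytest.approx(1.0)

    def test_reference_et_in_summer_range(self):
        weather = syn.generate_weather(syn.SeasonConfig(seed=0))
        overpass = weather[weather["doy"].isin((178, 194, 202, 218, 234, 258))]
        assert overpass["etr24"].between(3.0, 11.0).all()
        assert overpass["etr_inst"].between(0.3, 1.2).all()

    def test_lai_trajectory_shape(self):
        cfg = syn.SeasonConfig(seed=0)
        values = {d: syn.lai_trajectory(cfg, d) for d in (154, 178, 202, 218, 258)}
        assert values[154] < 1.0
        assert values[202] > 6.0
        assert values[218] == pytest.approx(cfg.lai_peak, abs=0.1)
        assert values[258] == pytest.approx(cfg.lai_senescent, abs=0.1)

    def test_deficit_sites_lower_lai_warmer_surface(self):
        cfg = syn.SeasonConfig(seed=0)
        _, truth = syn.generate_scene(cfg, 202)
        sites = {s.name: s for s in cfg.sites}
        lai_at = {n: truth.lai[s.row, s.col] for n, s in sites.items()}
        ts_at = {n: truth.ts[s.row, s.col] for n, s in sites.items()}
        for dry in ("N", "S-E"):
            assert lai_at[dry] < lai_at["S"]
            assert ts_at[dry] > ts_at["S"]

    def test_surface_temperature_in_study_range(self):
        cfg = syn.SeasonConfig(seed=0)
        for doy in cfg.overpass_doys:
            _, truth = syn.generate_scene(cfg, doy)
            ts_c = truth.ts - 273.15
            assert ts_c.min() > 12.0 and ts_c.max() < 36.0

    def test_out_of_season_rejected(self):
        with pytest.raises(ValueError, match="season"):
            syn.generate_scene(syn.SeasonConfig(seed=0), 10)


class TestForwardInverse:
    def test_lai_round_trip_zero_noise(self, zero_noise_season):
        _, _, truths, _, results = zero_noise_season
        for truth, result in zip(truths, results):
            rmse = np.sqrt(np.nanmean((result.lai - truth.lai_capped) ** 2))
            assert rmse < 0.05

    def test_ts_round_trip_zero_noise(self, zero_noise_season):
        _, _, truths, _, results = zero_noise_season
        for truth, result in zip(truths, results):
            rmse = np.sqrt(np.nanmean((result.ts - truth.ts) ** 2))
            assert rmse < 0.01

    def test_reflectances_satisfy_savi_identity(self):
        scene, truth = syn.generate_scene(syn.SeasonConfig(seed=6), 218)
        savi = radiometry.compute_savi(scene.nir, scene.red)
        assert np.allclose(savi, radiometry.savi_from_lai(truth.lai), atol=1e-9)


class TestGroundTruth:
    def test_zero_noise_measurements_equal_truth(self, zero_noise_season):
        cfg, _, truths, _, _ = zero_noise_season
        insitu = syn.generate_ground_truth(cfg, truths)
        sites = {s.name: s for s in cfg.sites}
        for truth in truths:
            rows = insitu["lai"][insitu["lai"]["doy"] == truth.doy]
            for _, row in rows.iterrows():
                s = sites[row["location"]]
                block = truth.lai[s.row - 1: s.row + 2, s.col - 1: s.col + 2]
                assert row["measured"] == pytest.approx(block.mean(), abs=1e-12)

    def test_measurements_converge_to_truth_with_noise(self):
        # instrument noise shifts measurements from truth by its own scale
        cfg = syn.SeasonConfig(seed=8)
        _, truths, _ = syn.generate_season(cfg)
        noisy = syn.generate_ground_truth(cfg, truths)
        quiet = syn.generate_ground_truth(cfg.zero_noise(), truths)
        diff = noisy["ts"]["measured"] - quiet["ts"]["measured"]
        assert 0.1 < diff.abs().mean() < 2.0

    def test_lai_r2_band_across_seeds(self):
        # Monte-Carlo check of the instrument-noise model: seasonal LAI
        # agreement between retrieved maps and noisy plot measurements
        from metricet import validation_stats as vs

        r2s = []
        for seed in range(20):
            cfg = syn.SeasonConfig(seed=seed)
            weather = syn.generate_weather(cfg)
            rasters, measurements = {}, []
            truths = []
            for doy in cfg.overpass_doys:
                scene, truth = syn.generate_scene(cfg, doy, weather)
                savi = radiometry.compute_savi(scene.nir, scene.red)
                rasters[doy] = radiometry.compute_lai(savi)
                truths.append(truth)
            insitu = syn.generate_ground_truth(cfg, truths)
            comp = vs.build_comparison(rasters, syn.site_pixels(cfg), insitu["lai"])
            r2s.append(vs.r_squared(comp))
        assert all(0.7 < r2 < 1.0 for r2 in r2s)
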