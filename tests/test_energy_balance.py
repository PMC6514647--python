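"""Net radiation, soil heat flux, aerodynamics, CIMEC calibration, closure."""

import numpy as np
import pytest

from metricet import energy_balance as eb
from metricet import pipeline as pl
from metricet import synthetic_scenes as syn


def arr(*values):
    return np.asarray(values, dtype=float).reshape(1, -1)


class TestNetRadiation:
    def test_hand_assembly(self):
        rad = eb.RadiationInputs(rs_down=800.0, air_temp=295.0, rl_down=350.0)
        # RL_up would be eps0 sigma Ts^4; pick Ts so RL_up = 450 exactly
        ts = (450.0 / (0.98 * eb.STEFAN_BOLTZMANN)) ** 0.25
        rn = eb.net_radiation(arr(0.2), arr(ts), arr(0.98), rad)
        assert rn[0, 0] == pytest.approx(800 - 160 + 350 - 450 - 0.02 * 350, abs=1e-9)

    def test_balanced_zero(self):
        rad = eb.RadiationInputs(rs_down=0.0, air_temp=295.0, rl_down=300.0)
        ts = (300.0 / eb.STEFAN_BOLTZMANN) ** 0.25
        rn = eb.net_radiation(arr(0.5), arr(ts), arr(1.0), rad)
        assert rn[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_stefan_boltzmann_upwelling(self):
        rad = eb.RadiationInputs(rs_down=0.0, air_temp=295.0, rl_down=1.0)
        rn = eb.net_radiation(arr(0.0), arr(300.0), arr(0.98), rad)
        rl_up = 1.0 - rn[0, 0] - (1 - 0.98) * 1.0  # invert the assembly
        assert rl_up == pytest.approx(450.06, abs=0.03)

    def test_negative_shortwave_rejected(self):
        with pytest.raises(ValueError, match="rs_down"):
            eb.RadiationInputs(rs_down=-5.0, air_temp=295.0)


class TestSoilHeatFlux:
    def test_dense_canopy_branch(self):
        g = eb.soil_heat_flux(arr(600.0), arr(2.0), arr(300.0))
        assert g[0, 0] == pytest.approx(68.09, abs=0.01)

    def test_sparse_canopy_branch(self):
        g = eb.soil_heat_flux(arr(400.0), arr(0.2), arr(300.16))
        assert g[0, 0] == pytest.approx(82.2, abs=1e-9)

    def test_boundary_belongs_to_dense_branch(self):
        g = eb.soil_heat_flux(arr(500.0), arr(0.5), arr(300.0))
        assert g[0, 0] == pytest.approx(94.36, abs=0.01)

    def test_sparse_branch_zero_rn_masked(self):
        g = eb.soil_heat_flux(arr(0.0), arr(0.2), arr(300.0))
        assert np.isnan(g[0, 0])


class TestAerodynamics:
    def test_hand_values(self):
        aero = eb.aerodynamic_state(2.0, 0.03, arr(3.0))
        assert aero.u200 == pytest.approx(4.1931, abs=2e-4)
        assert aero.u_star[0, 0] == pytest.approx(0.20922, abs=2e-5)
        assert aero.rah[0, 0] == pytest.approx(34.92, abs=0.01)

    def test_roughness_floor(self):
        aero = eb.aerodynamic_state(2.0, 0.03, arr(0.0))
        assert aero.zom[0, 0] == 0.005

    def test_neutral_proportionality(self):
        one = eb.aerodynamic_state(2.0, 0.03, arr(3.0))
        two = eb.aerodynamic_state(4.0, 0.03, arr(3.0))
        assert two.u_star[0, 0] == pytest.approx(2 * one.u_star[0, 0], rel=1e-12)
        assert two.rah[0, 0] == pytest.approx(one.rah[0, 0] / 2, rel=1e-12)

    def test_nonpositive_wind_rejected(self):
        with pytest.raises(ValueError, match="wind_speed"):
            eb.aerodynamic_state(0.0, 0.03, arr(3.0))

    def test_air_density_default_and_ideal_gas(self):
        assert eb.air_density() == 1.15
        rho = eb.air_density(298.15, 495.0)
        assert 1.05 < rho < 1.15


def _two_pixel_setup():
    """Cold pixel at index (0,0), hot at (0,1), fixed rah=20, rho*Cp=1154.6."""
    rn = arr(560.0, 530.0)
    g = arr(60.0, 80.0)  # Rn-G = 500 (cold), 450 (hot)
    ts = arr(295.0, 315.0)
    aero = eb.AerodynamicState(rho_air=1.15, wind_speed=2.0, u200=4.0,
                               zom=np.full((1, 2), 0.05),
                               u_star=np.full((1, 2), 0.2),
                               rah=np.full((1, 2), 20.0))
    anchors = eb.CalibrationAnchors(cold_index=(0, 0), hot_index=(0, 1))
    return rn, g, ts, aero, anchors


class TestCalibrateDT:
    def test_single_pass_hand_evaluation(self):
        rn, g, ts, aero, anchors = _two_pixel_setup()
        out = eb.calibrate_dT(rn, g, ts, anchors, aero, etr_inst=0.8)
        # exact values with lambda(295 K) from the latent-heat relation
        assert out.b == pytest.approx(0.4517015, abs=1e-6)
        assert out.a == pytest.approx(-134.4911, abs=1e-3)
        # the classical hand evaluation rounds lambda to 2.45e6 J/kg
        assert out.a == pytest.approx(-134.53, abs=0.05)
        assert out.b == pytest.approx(0.45182, abs=2e-4)

    def test_symmetric_anchors_give_flat_line(self):
        rn = arr(500.0, 500.0)
        g = arr(50.0, 50.0)
        ts = arr(295.0, 315.0)
        _, _, _, aero, _ = _two_pixel_setup()
        anchors = eb.CalibrationAnchors((0, 0), (0, 1), etrf_cold=0.5, etrf_hot=0.5)
        out = eb.calibrate_dT(rn, g, ts, anchors, aero, etr_inst=0.8)
        # same available energy and same anchor ETrF at both ends, up to the
        # small lambda(Ts) difference between the two anchor temperatures
        assert out.b == pytest.approx(0.0, abs=5e-3)

    def test_degenerate_anchors_rejected(self):
        rn, g, ts, aero, anchors = _two_pixel_setup()
        ts_flat = arr(300.0, 300.0)
        with pytest.raises(ValueError, match="degenerate"):
            eb.calibrate_dT(rn, g, ts_flat, anchors, aero, etr_inst=0.8)

    def test_anchor_h_reproduced_by_line(self):
        rn, g, ts, aero, anchors = _two_pixel_setup()
        out = eb.calibrate_dT(rn, g, ts, anchors, aero, etr_inst=0.8)
        h = eb.sensible_heat_flux(ts, out, aero)
        le_cold = 1.05 * 0.8 * (2.501 - 0.00236 * (295 - 273.15)) * 1e6 / 3600
        assert h[0, 0] == pytest.approx(float(rn[0, 0] - g[0, 0]) - le_cold, abs=0.1)
        assert h[0, 1] == pytest.approx(float(rn[0, 1] - g[0, 1]), abs=0.1)


class TestSensibleHeat:
    def test_hand_value(self):
        aero = eb.AerodynamicState(rho_air=1.15, wind_speed=2.0, u200=4.0,
                                   zom=arr(0.05), u_star=arr(0.2), rah=arr(20.0))
        anchors = eb.CalibrationAnchors((0, 0), (0, 0), a=5.0, b=0.0)
        h = eb.sensible_heat_flux(arr(300.0), anchors, aero)
        assert h[0, 0] == pytest.approx(288.65, abs=1e-9)

    def test_zero_dT_gives_zero_flux(self):
        aero = eb.AerodynamicState(rho_air=1.15, wind_speed=2.0, u200=4.0,
                                   zom=arr(0.05, 0.1), u_star=arr(0.2, 0.3),
                                   rah=arr(20.0, 55.0))
        anchors = eb.CalibrationAnchors((0, 0), (0, 1), a=0.0, b=0.0)
        assert np.all(eb.sensible_heat_flux(arr(300.0, 320.0), anchors, aero) == 0.0)

    def test_uncalibrated_anchors_rejected(self):
        aero = eb.AerodynamicState(rho_air=1.15, wind_speed=2.0, u200=4.0,
                                   zom=arr(0.05), u_star=arr(0.2), rah=arr(20.0))
        with pytest.raises(ValueError, match="calibrate"):
            eb.sensible_heat_flux(arr(300.0), eb.CalibrationAnchors((0, 0), (0, 0)), aero)

    def test_monotone_in_ts_for_positive_slope(self):
        aero = eb.AerodynamicState(rho_air=1.15, wind_speed=2.0, u200=4.0,
                                   zom=np.full((1, 5), 0.05), u_star=np.full((1, 5), 0.2),
                                   rah=np.full((1, 5), 20.0))
        anchors = eb.CalibrationAnchors((0, 0), (0, 4), a=-100.0, b=0.4)
        ts = np.linspace(290, 320, 5).reshape(1, -1)
        h = eb.sensible_heat_flux(ts, anchors, aero)
        assert np.all(np.diff(h[0]) > 0)

    def test_neutral_limit_matches_closed_form(self):
        rn, g, ts, aero, anchors = _two_pixel_setup()
        h, out, _ = eb.solve_sensible_heat(rn, g, ts, anchors, aero, 0.8, stability=False)
        closed = aero.rho_air * aero.cp * (out.a + out.b * ts) / aero.rah
        assert np.allclose(h, closed, atol=1e-12)


class TestStabilityIteration:
    def test_psi_neutral_limit_is_zero(self):
        L = np.array([np.inf, -np.inf])
        for z, blend in ((200.0, True), (2.0, False), (0.1, False)):
            assert np.allclose(eb._psi_terms(L, z, blend), 0.0)

    def test_unstable_reduces_resistance(self):
        L = np.array([-10.0])
        psi_m = eb._psi_terms(L, 200.0, True)
        psi_h = eb._psi_terms(L, 2.0, False)
        assert psi_m[0] > 0 and psi_h[0] > 0  # positive psi -> smaller rah

    def test_stable_increases_resistance(self):
        L = np.array([50.0])
        assert eb._psi_terms(L, 2.0, False)[0] < 0

    def test_converges_on_synthetic_scene(self):
        cfg = syn.SeasonConfig(seed=2)
        scenes, _, weather = syn.generate_season(cfg)
        scene = scenes[2]
        row = weather.loc[weather["doy"] == scene.acquisition_doy].iloc[0]
        result = pl.process_scene(scene, row, pl.ProcessParams())
        assert result.anchors.converged
        # calibrated line still reproduces the anchor conditions exactly
        assert result.report["etrf_cold_anchor"] == pytest.approx(1.05, abs=0.02)
        assert result.report["etrf_hot_anchor"] == pytest.approx(0.0, abs=0.02)


class TestClosure:
    def test_arithmetic(self):
        le = eb.close_balance(arr(600.0), arr(68.0), arr(289.0))
        assert le[0, 0] == 243.0

    def test_zero_when_balanced(self):
        assert eb.close_balance(arr(357.0), arr(57.0), arr(300.0))[0, 0] == 0.0

    def test_conservation_identity(self):
        rng = np.random.default_rng(0)
        rn, g, h = rng.normal(400, 100, (3, 8, 8))
        le = eb.close_balance(rn, g, h)
        assert np.allclose(rn - (g + h + le), 0.0, atol=1e-9)


class TestAnchorSelection:
    def _fields(self):
        rng = np.random.default_rng(1)
        ts = 300.0 + rng.normal(0, 0.5, (20, 20))
        ndvi = 0.5 + rng.normal(0, 0.02, (20, 20))
        lai = np.full((20, 20), 3.0)
        ts[4, 5], ndvi[4, 5] = 292.0, 0.85  # planted cold, high NDVI
        ts[15, 16], ndvi[15, 16] = 312.0, 0.05  # planted hot, bare
        return ts, lai, ndvi

    def test_finds_planted_extremes(self):
        ts, lai, ndvi = self._fields()
        anchors = eb.select_calibration_pixels(ts, lai, ndvi)
        assert anchors.cold_index == (4, 5)
        assert anchors.hot_index == (15, 16)

    def test_uniform_fields_tie_break_row_major(self):
        ts = np.full((15, 15), 300.0)
        ndvi = np.full((15, 15), 0.5)
        anchors = eb.select_calibration_pixels(ts, ts, ndvi)
        assert anchors.cold_index == (0, 0) and anchors.hot_index == (0, 0)

    def test_manual_override_verbatim(self):
        ts, lai, ndvi = self._fields()
        anchors = eb.select_calibration_pixels(ts, lai, ndvi, manual=((1, 2), (3, 4)))
        assert anchors.cold_index == (1, 2) and anchors.hot_index == (3, 4)

    def test_too_few_pixels(self):
        with pytest.raises(ValueError, match="100"):
            eb.select_calibration_pixels(np.full((5, 5), 300.0), np.ones((5, 5)),
                                         np.full((5, 5), 0.5))
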