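"""Synthetic Landsat-like season generator.

Emulates a single rain-fed corn field over a growing season — five named
observation plots, six overpass dates (DOY 178-258, alternating between the
two sensors), a leaf-area trajectory rising from ~0.3 to a ~6.8 peak and
senescing to ~3.5, surface temperatures of roughly 19-31 C, and daily ETa in
the 2-10 mm range — with two plots (N and S-E) degraded by an elevation-driven
moisture deficit (lower LAI, warmer canopy).

Scenes are built by running the retrieval physics forward: a smooth LAI field
is converted to (red, NIR) reflectance through the exact SAVI inverse plus a
soil-line split, the temperature field is converted to thermal radiance
through the exact Planck inverse, and the truth energy balance (net radiation,
soil heat flux, neutral-stability sensible heat from a planted hot/cold anchor
pair) yields the truth ET fields. Running the processing pipeline on such a
scene at zero noise must reproduce every truth raster to numerical precision —
the central round-trip oracle of the package. Site plots are 3x3-pixel
plateaus so the nine-pixel sampling rule reads plateau values exactly.

Everything is a pure function of (config, seed); identical seeds give
bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import energy_balance as eb
from . import et_mapping, radiometry, reference_kc, thermal
from .rasters import Grid


@dataclass(frozen=True)
class SitePlot:
    """One instrumented 30 m plot: grid position plus its local modifiers
    (moisture-deficit LAI multiplier, canopy-temperature offset, elevation
    offset relative to the field base)."""

    name: str
    row: int
    col: int
    lai_factor: float = 1.0
    ts_offset_k: float = 0.0
    elevation_offset_m: float = 0.0


def _default_sites() -> tuple[SitePlot, ...]:
    # N and S-E sit higher (per the field's relief) and run drier: reduced
    # canopy and a warmer surface. The others get small distinct modifiers so
    # within-date site variance is nonzero even at zero noise.
    return (
        SitePlot("S-E", 30, 26, lai_factor=0.88, ts_offset_k=1.2, elevation_offset_m=3.0),
        SitePlot("S", 30, 16, lai_factor=1.00, ts_offset_k=-0.2, elevation_offset_m=1.0),
        SitePlot("N", 8, 20, lai_factor=0.91, ts_offset_k=0.9, elevation_offset_m=9.0),
        SitePlot("E", 18, 28, lai_factor=0.97, ts_offset_k=0.1, elevation_offset_m=1.0),
        SitePlot("E-E", 22, 34, lai_factor=0.94, ts_offset_k=0.4, elevation_offset_m=0.0),
    )


#: sensor per overpass date (alternating ETM+ / OLI-TIRS, as in the study year)
DEFAULT_SENSORS = {178: "L7", 194: "L7", 202: "L8", 218: "L8", 234: "L8", 258: "L7"}


@dataclass(frozen=True)
class SeasonConfig:
    """Study-season generator settings. Defaults are the emulated study
    conditions; ``zero_noise()`` derives the exactness variant used by the
    round-trip oracles."""

    seed: int = 0
    rows: int = 40
    cols: int = 40
    pixel_size: float = 30.0
    overpass_doys: tuple[int, ...] = (178, 194, 202, 218, 234, 258)
    season_start_doy: int = 150
    season_end_doy: int = 260
    sites: tuple[SitePlot, ...] = field(default_factory=_default_sites)
    elevation: float = 495.0  # m, field base
    station_zom: float = 0.03  # m, weather-station (grass) roughness
    # canopy trajectory
    lai_start: float = 0.3
    lai_peak: float = 6.8
    lai_senescent: float = 3.5
    rise_midpoint_doy: int = 176
    rise_scale_days: float = 7.0
    senescence_start_doy: int = 226
    # thermal structure
    bare_soil_excess_k: float = 11.0  # midsummer bare-minus-vegetated Ts span
    # winds at overpass (m s-1)
    high_wind_doy: int = 194
    high_wind: float = 5.9
    low_wind: float = 1.0
    # spatial noise (correlated Gaussian fields, correlation length ~3 px)
    lai_noise_sd: float = 0.25
    ts_noise_sd: float = 0.3
    noise_correlation_px: float = 3.0
    # instrument noise on site measurements
    lai_meas_sd: float = 0.3
    ts_meas_sd: float = 0.5
    eta_meas_sd: float = 0.35

    def zero_noise(self) -> "SeasonConfig":
        """Exactness variant: all noise off, canopy peak kept below the LAI=6
        retrieval cap (the forward map is only invertible below the cap), and
        site LAI multipliers <= 1 so no plot crosses it."""
        sites = tuple(replace(s, lai_factor=min(s.lai_factor, 1.0)) for s in self.sites)
        return replace(
            self, lai_peak=5.8, sites=sites,
            lai_noise_sd=0.0, ts_noise_sd=0.0,
            lai_meas_sd=0.0, ts_meas_sd=0.0, eta_meas_sd=0.0,
        )

    @property
    def grid(self) -> Grid:
        return Grid(rows=self.rows, cols=self.cols, pixel_size=self.pixel_size)

    @property
    def cold_index(self) -> tuple[int, int]:
        return (2, 2)

    @property
    def hot_index(self) -> tuple[int, int]:
        return (self.rows - 3, self.cols - 3)


@dataclass
class TruthRasters:
    """Generating fields carried alongside a synthetic scene."""

    doy: int
    lai: np.ndarray  # generating LAI (may exceed the retrieval cap)
    lai_capped: np.ndarray  # min(LAI, 6): what an exact retrieval returns
    ts: np.ndarray  # K
    etrf: np.ndarray
    eta: np.ndarray  # mm day-1
    anchors: eb.CalibrationAnchors
    weather: pd.Series


# ---------------------------------------------------------------------------
# seasonal drivers


def lai_trajectory(cfg: SeasonConfig, doy: int) -> float:
    """Field-mean LAI: logistic green-up to the peak, linear senescence."""
    rise = cfg.lai_start + (cfg.lai_peak - cfg.lai_start) / (
        1.0 + np.exp(-(doy - cfg.rise_midpoint_doy) / cfg.rise_scale_days)
    )
    if doy <= cfg.senescence_start_doy:
        return float(rise)
    frac = (doy - cfg.senescence_start_doy) / (cfg.season_end_doy - 2 - cfg.senescence_start_doy)
    return float(cfg.lai_peak - min(frac, 1.0) * (cfg.lai_peak - cfg.lai_senescent))


def _air_temp_c(doy: int) -> float:
    """Mid-continent summer air temperature at overpass time (C)."""
    return 15.0 + 11.0 * float(np.exp(-(((doy - 198.0) / 40.0) ** 2)))


def _rs_down(doy: int) -> float:
    """Clear-sky instantaneous shortwave at overpass (W m-2)."""
    return 600.0 + 350.0 * float(np.cos(2.0 * np.pi * (doy - 172.0) / 365.0))


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int], sd: float,
                      correlation_px: float) -> np.ndarray:
    if sd <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=correlation_px, mode="wrap")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def _rng(cfg: SeasonConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


# ---------------------------------------------------------------------------
# weather


def generate_weather(cfg: SeasonConfig) -> pd.DataFrame:
    """Daily weather/reference-ET table for the season.

    One record per day with overpass-time instantaneous values (shortwave,
    air temperature, wind, vapor pressure) plus standardized tall-reference
    ETr: instantaneous (mm h-1, from the hourly form) and cumulative daily
    (mm day-1, from the daily form). The configured high-wind overpass day
    carries 5.9 m s-1; other overpass days ~1.0 m s-1; non-overpass days get a
    moderate seasonal breeze. ``atmometer_etr`` tracks daily ETr with a small
    deterministic low bias, mimicking the device's muted wind response.
    """
    rows = []
    rng = _rng(cfg, 7)
    for doy in range(cfg.season_start_doy, cfg.season_end_doy + 1):
        rs = _rs_down(doy)
        ta = _air_temp_c(doy)
        if doy == cfg.high_wind_doy:
            u = cfg.high_wind
        elif doy in cfg.overpass_doys:
            u = cfg.low_wind
        else:
            u = 2.0 + 1.5 * rng.random()
        ea = 0.50 * float(reference_kc.saturation_vapor_pressure(ta))
        rn_hour_mj = 0.7 * rs * 3600.0 / 1e6
        etr_inst = reference_kc.asce_pm_etr(
            ta, u, ea, rn_hour_mj, elevation=cfg.elevation, hourly=True, daytime=True
        )
        rs_daily_mj = rs * 0.0275
        rn_daily_mj = 0.75 * rs_daily_mj - 1.2
        etr24 = reference_kc.asce_pm_etr(
            ta - 2.0, max(u, 3.0), ea, rn_daily_mj, elevation=cfg.elevation, hourly=False
        )
        rows.append({
            "timestamp": f"2016-{doy:03d}", "doy": doy, "rs_down": rs, "ta": ta,
            "u": u, "ea": ea, "etr_inst": etr_inst, "etr24": etr24,
            "atmometer_etr": 0.93 * etr24,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenes


def generate_scene(
    cfg: SeasonConfig, doy: int, weather: pd.DataFrame | None = None
) -> tuple[radiometry.Scene, TruthRasters]:
    """Forward-model one overpass into a Scene plus its truth rasters."""
    if not (cfg.season_start_doy <= doy <= cfg.season_end_doy):
        raise ValueError(f"DOY {doy} outside season [{cfg.season_start_doy}, {cfg.season_end_doy}]")
    if weather is None:
        weather = generate_weather(cfg)
    w = weather.loc[weather["doy"] == doy].iloc[0]
    sensor = DEFAULT_SENSORS.get(doy, "L8")
    rng = _rng(cfg, 11, doy)
    shape = (cfg.rows, cfg.cols)

    # --- canopy field: base trajectory + correlated noise + site plateaus
    base = lai_trajectory(cfg, doy)
    lai = np.full(shape, base) + _correlated_field(rng, shape, cfg.lai_noise_sd,
                                                  cfg.noise_correlation_px)
    for s in cfg.sites:
        lai[s.row - 1: s.row + 2, s.col - 1: s.col + 2] = base * s.lai_factor
    lai = np.clip(lai, 0.05, None)

    # --- surface temperature: vegetated surface near air temperature, bare
    # soil warmer in proportion to available shortwave; deficit plots warmer
    ta_k = float(w["ta"]) + 273.15
    excess = cfg.bare_soil_excess_k * float(w["rs_down"]) / 950.0
    canopy_frac = np.clip(lai / 6.5, 0.0, 1.0)
    ts = ta_k + 1.0 + excess * (1.0 - canopy_frac)
    ts += _correlated_field(_rng(cfg, 13, doy), shape, cfg.ts_noise_sd, cfg.noise_correlation_px)
    for s in cfg.sites:
        site_frac = min(base * s.lai_factor / 6.5, 1.0)
        ts[s.row - 1: s.row + 2, s.col - 1: s.col + 2] = (
            ta_k + 1.0 + excess * (1.0 - site_frac) + s.ts_offset_k
        )

    # --- plant the calibration extremes: a well-watered full-cover pixel
    # (coolest of the high-NDVI population) and a dry bare pixel (warmest of
    # the low-NDVI population), so automatic anchor selection is unambiguous
    ci, hi = cfg.cold_index, cfg.hot_index
    lai[ci] = float(lai.max()) + 0.1
    lai[hi] = 0.02
    ts[ci] = float(np.delete(ts.reshape(-1), [ci[0] * cfg.cols + ci[1]]).min()) - 1.0
    ts[hi] = float(ts.max()) + 2.0

    # --- reflectances via the exact SAVI inverse and a soil-line split
    lai_capped = np.minimum(lai, radiometry.LAI_CAP)
    savi = radiometry.savi_from_lai(lai)
    red = np.clip(0.25 - 0.028 * lai, 0.02, None)
    L = radiometry.SAVI_L
    nir = (savi * (L + red) + (1.0 + L) * red) / ((1.0 + L) - savi)
    ndvi = radiometry.compute_ndvi(nir, red)
    albedo = 0.23 - 0.045 * (1.0 - np.exp(-0.5 * lai_capped))

    emis = radiometry.compute_emissivities(lai_capped, ndvi, albedo)
    constants = thermal.SENSOR_CONSTANTS[sensor]
    radiance = thermal.radiance_from_temperature(ts, emis.eps_nb, constants)

    scene = radiometry.Scene(
        sensor=sensor, acquisition_doy=int(doy), red=red, nir=nir,
        thermal_radiance=radiance, albedo=albedo, grid=cfg.grid,
    )

    # --- truth energy balance (neutral stability), anchored at the planted
    # extreme pixels exactly as the calibration assumes
    rho = eb.air_density(ta_k, cfg.elevation)
    rad = eb.RadiationInputs(rs_down=float(w["rs_down"]), air_temp=ta_k, elevation=cfg.elevation)
    rn = eb.net_radiation(albedo, ts, emis.eps_0, rad)
    g = eb.soil_heat_flux(rn, lai_capped, ts)
    aero = eb.aerodynamic_state(float(w["u"]), cfg.station_zom, lai_capped, rho_air=rho)
    anchors = eb.CalibrationAnchors(cold_index=ci, hot_index=hi)
    anchors = eb.calibrate_dT(rn, g, ts, anchors, aero, float(w["etr_inst"]))
    h = eb.sensible_heat_flux(ts, anchors, aero)
    le = eb.close_balance(rn, g, h)
    et_inst = et_mapping.et_instantaneous(le, ts)
    etrf = et_mapping.reference_et_fraction(et_inst, float(w["etr_inst"]))
    eta = et_mapping.et_daily(etrf, float(w["etr24"]))

    truth = TruthRasters(doy=int(doy), lai=lai, lai_capped=lai_capped, ts=ts,
                         etrf=etrf, eta=eta, anchors=anchors, weather=w)
    return scene, truth


def generate_season(
    cfg: SeasonConfig,
) -> tuple[list[radiometry.Scene], list[TruthRasters], pd.DataFrame]:
    """All overpass scenes plus the season weather table."""
    weather = generate_weather(cfg)
    scenes, truths = [], []
    for doy in cfg.overpass_doys:
        scene, truth = generate_scene(cfg, doy, weather)
        scenes.append(scene)
        truths.append(truth)
    return scenes, truths, weather


# ---------------------------------------------------------------------------
# ground truth


def generate_ground_truth(
    cfg: SeasonConfig, truths: list[TruthRasters]
) -> dict[str, pd.DataFrame]:
    """Site-level "measurements" for the three compared variables.

    Each value is the 3x3 plot mean of the truth raster plus instrument noise:
    ceptometer LAI (sd 0.3), infrared-thermometer surface temperature in C
    (sd 0.5, reflecting a +/-2 C instrument averaged over ten readings), and
    daily ETa (sd 0.35 mm, the atmometer-plus-crop-coefficient error level).
    Returns one ``doy, location, measured`` table per variable.
    """
    out = {v: [] for v in ("lai", "ts", "eta")}
    for truth in truths:
        rng = _rng(cfg, 17, truth.doy)
        for s in cfg.sites:
            block = np.s_[s.row - 1: s.row + 2, s.col - 1: s.col + 2]
            noise = rng.standard_normal(3)
            out["lai"].append({
                "doy": truth.doy, "location": s.name,
                "measured": float(truth.lai[block].mean()) + cfg.lai_meas_sd * noise[0],
            })
            out["ts"].append({
                "doy": truth.doy, "location": s.name,
                "measured": float(truth.ts[block].mean()) - 273.15 + cfg.ts_meas_sd * noise[1],
            })
            out["eta"].append({
                "doy": truth.doy, "location": s.name,
                "measured": max(float(truth.eta[block].mean()) + cfg.eta_meas_sd * noise[2], 0.0),
            })
    return {v: pd.DataFrame(rows) for v, rows in out.items()}


def site_pixels(cfg: SeasonConfig) -> dict[str, tuple[int, int]]:
    """Site name -> (row, col) mapping used by the nine-pixel sampling rule."""
    return {s.name: (s.row, s.col) for s in cfg.sites}
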