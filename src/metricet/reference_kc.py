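"""Alfalfa-reference ET, crop-coefficient curve, and atmometer-based ETa.

The ground-truth arm of the study: a standardized Penman-Monteith tall-crop
(alfalfa) reference ET from station weather, a piecewise-linear corn Kc curve
anchored at effective cover (~55 days after emergence), and actual ET as
ETa = ETr * Kc — the atmometer/crop-coefficient estimate the energy-balance
maps are compared against. Also holds the weather-series quality-control
screen (range and ordering flags; flagged records are excluded, never imputed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SOLAR_CONSTANT = 1367.0  # W m-2

#: expected weather CSV columns (etr/atmometer columns optional)
WEATHER_COLUMNS = ["timestamp", "rs_down", "ta", "u", "ea"]


# ---------------------------------------------------------------------------
# ASCE standardized Penman-Monteith, tall (alfalfa) reference


def saturation_vapor_pressure(t_c: float | np.ndarray) -> float | np.ndarray:
    """es(T) = 0.6108 exp(17.27 T / (T + 237.3)) kPa, T in Celsius."""
    t_c = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


def asce_pm_etr(
    temp_c: float,
    u2: float,
    ea_kpa: float,
    rn_mj: float,
    g_mj: float = 0.0,
    elevation: float = 0.0,
    hourly: bool = False,
    daytime: bool = True,
) -> float:
    """Standardized-form tall-reference ET for one step (mm day-1 or mm h-1).

    ETr = (0.408 D (Rn - G) + g Cn u2 (es - ea) / (T + 273)) / (D + g (1 + Cd u2))

    with D the saturation-slope (kPa C-1), g the psychrometric constant from
    station pressure, and the tall-crop numerator/denominator constants
    Cn = 1600, Cd = 0.38 daily; Cn = 66, Cd = 0.25 (daytime) / 1.7 (nighttime)
    hourly. Rn and G in MJ m-2 per step.
    """
    for name, v in (("temp_c", temp_c), ("u2", u2), ("ea_kpa", ea_kpa), ("rn_mj", rn_mj)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"asce_pm_etr: missing or non-finite input {name!r}")
    if hourly:
        cn, cd = 66.0, (0.25 if daytime else 1.7)
    else:
        cn, cd = 1600.0, 0.38
    p_kpa = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * p_kpa
    es = float(saturation_vapor_pressure(temp_c))
    delta = 4098.0 * es / (temp_c + 237.3) ** 2
    num = 0.408 * delta * (rn_mj - g_mj) + gamma * (cn / (temp_c + 273.0)) * u2 * (es - ea_kpa)
    etr = num / (delta + gamma * (1.0 + cd * u2))
    return max(float(etr), 0.0)


# ---------------------------------------------------------------------------
# crop coefficient curve


@dataclass
class KcCurve:
    """Piecewise-linear alfalfa-basis Kc curve on a days-after-emergence axis.

    The default corn shape: initial Kc 0.25 at emergence, linear rise to the
    peak (1.0) at effective cover 55 DAE, flat through mid-season, declining
    to 0.5 at maturity. All knots are data, editable in the run config; they
    approximate the published curve's shape, not tabulated study values.
    """

    emergence_doy: int
    effective_cover_dae: int = 55
    peak_kc: float = 1.0
    breakpoints: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.breakpoints:
            self.breakpoints = [
                (0.0, 0.25),
                (float(self.effective_cover_dae), self.peak_kc),
                (95.0, self.peak_kc),
                (120.0, 0.5),
            ]
        self.breakpoints = sorted(self.breakpoints)
        if any(kc < 0 for _, kc in self.breakpoints):
            raise ValueError("Kc breakpoints must be non-negative")


def kc_at(curve: KcCurve, doy: int) -> float:
    """Kc on a calendar day by linear interpolation of the DAE breakpoints;
    days before emergence return the initial value (with a warning), days past
    the last knot hold the final value."""
    dae = doy - curve.emergence_doy
    xs = np.array([d for d, _ in curve.breakpoints])
    ys = np.array([k for _, k in curve.breakpoints])
    if dae < xs[0]:
        log.warning("kc_at: DOY %d is before emergence (DOY %d); returning initial Kc",
                    doy, curve.emergence_doy)
        return float(ys[0])
    return float(np.interp(dae, xs, ys))


def atmometer_eta(etr: float | np.ndarray, kc: float | np.ndarray) -> float | np.ndarray:
    """ETa = ETr * Kc (mm day-1): the atmometer/crop-coefficient actual ET."""
    etr = np.asarray(etr, dtype=float)
    kc = np.asarray(kc, dtype=float)
    if np.any(etr < 0) or np.any(kc < 0):
        raise ValueError("ETr and Kc must be non-negative")
    out = etr * kc
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# weather series QC


def qc_weather(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Range/ordering screen of a weather table.

    Checks: rs_down in [0, 1367], ta in [-40, 50] C, u in [0, 30] m s-1,
    ea >= 0, strictly increasing timestamps. Offending records are flagged and
    excluded from the cleaned series (never imputed). Returns
    ``(clean, report)`` with per-variable flag counts.
    """
    df = series.copy()
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather table is missing columns: {missing}")
    flags = pd.DataFrame(False, index=df.index, columns=["rs_down", "ta", "u", "ea", "ordering"])
    flags["rs_down"] = (df["rs_down"] < 0) | (df["rs_down"] > SOLAR_CONSTANT)
    flags["ta"] = (df["ta"] < -40) | (df["ta"] > 50)
    flags["u"] = (df["u"] < 0) | (df["u"] > 30)
    flags["ea"] = df["ea"] < 0
    ts = df["timestamp"]
    if ts.dtype == object:
        ts = pd.to_datetime(ts)
    if pd.api.types.is_datetime64_any_dtype(ts):
        increasing = ts.diff().iloc[1:] > pd.Timedelta(0)
    else:
        increasing = ts.astype(float).diff().iloc[1:] > 0
    flags.loc[df.index[1:], "ordering"] = ~increasing.to_numpy()
    any_flag = flags.any(axis=1)
    report = flags.sum(axis=0).rename("n_flagged").to_frame()
    if int(any_flag.sum()):
        log.info("qc_weather: flagged %d of %d records", int(any_flag.sum()), len(df))
    return df.loc[~any_flag].copy(), report
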