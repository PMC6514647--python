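"""Latent heat flux to instantaneous, daily, and seasonal ET products.

ETinst = 3600 LE / (lambda rho_w) in mm h-1, the reference-ET fraction
ETrF = ETinst / ETr_inst, daily ET24 = ETrF * ETr24, and season totals by
per-pixel linear interpolation of ETrF between image dates multiplied by the
daily reference series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rasters import check_same_shape
from .thermal import latent_heat_of_vaporization

log = logging.getLogger(__name__)

RHO_WATER = 1000.0  # kg m-3


@dataclass
class ETProducts:
    """ET rasters for one overpass."""

    doy: int
    et_inst: np.ndarray  # mm h-1
    etrf: np.ndarray  # unitless
    et24: np.ndarray  # mm day-1
    n_clamped_negative: int = 0
    n_etrf_high: int = 0
    rho_w: float = field(default=RHO_WATER, repr=False)


def et_instantaneous(le: np.ndarray, ts: np.ndarray, rho_w: float = RHO_WATER) -> np.ndarray:
    """ETinst = 3600 LE 1000 / (lambda(Ts) rho_w) mm h-1.

    For rho_w = 1000 kg m-3 the density division and the metre-to-millimetre
    conversion cancel, recovering the plain 3600 LE / lambda form; keeping both
    factors makes a non-default density behave dimensionally. Negative LE is
    clamped to 0 (counted and logged) so ET products stay physical while the
    energy-balance rasters remain diagnostic.
    """
    le = np.asarray(le, dtype=float)
    ts = np.asarray(ts, dtype=float)
    check_same_shape(le, ts)
    lam = latent_heat_of_vaporization(ts)
    et = 3600.0 * le * 1000.0 / (lam * rho_w)
    n_neg = int(np.sum(et < 0))
    if n_neg:
        log.info("et_instantaneous: clamped %d negative-LE pixels to 0", n_neg)
    return np.maximum(et, 0.0)


def reference_et_fraction(et_inst: np.ndarray, etr_inst: float) -> np.ndarray:
    """ETrF = ETinst / ETr_inst; values above 1.3 are retained but counted."""
    if etr_inst <= 0:
        raise ValueError(f"etr_inst must be > 0, got {etr_inst}")
    etrf = np.asarray(et_inst, dtype=float) / etr_inst
    n_hi = int(np.sum(etrf > 1.3))
    if n_hi:
        log.info("reference_et_fraction: %d pixels with ETrF > 1.3", n_hi)
    return etrf


def et_daily(etrf: np.ndarray, etr24: float) -> np.ndarray:
    """ET24 = ETrF * ETr24 (mm day-1), assuming the instantaneous fraction
    holds for the whole day."""
    if etr24 < 0:
        raise ValueError(f"etr24 must be >= 0, got {etr24}")
    return np.asarray(etrf, dtype=float) * etr24


def interpolate_season(
    etrf_by_doy: list[tuple[int, np.ndarray]],
    etr24_by_doy: dict[int, float],
) -> np.ndarray:
    """Seasonal ET (mm) over [first image DOY, last image DOY].

    ETrF is linearly interpolated per pixel to every day between consecutive
    image dates (constant-hold outside the image span, which is a no-op for
    the closed span used here), multiplied by that day's cumulative reference
    ETr24, and summed.
    """
    if not etrf_by_doy:
        raise ValueError("seasonal interpolation needs at least one image date")
    if len(etrf_by_doy) == 1:
        # degenerate span: the season collapses to the single image day
        doy, etrf = etrf_by_doy[0]
        if doy not in etr24_by_doy:
            raise ValueError(f"daily ETr24 series is missing days: [{doy}]")
        return np.asarray(etrf, dtype=float) * etr24_by_doy[doy]
    etrf_by_doy = sorted(etrf_by_doy, key=lambda p: p[0])
    doys = [d for d, _ in etrf_by_doy]
    if len(set(doys)) != len(doys):
        raise ValueError(f"duplicate image DOYs: {doys}")
    stack = np.stack([np.asarray(r, dtype=float) for _, r in etrf_by_doy])
    check_same_shape(*stack)
    days = list(range(doys[0], doys[-1] + 1))
    missing = [d for d in days if d not in etr24_by_doy]
    if missing:
        raise ValueError(f"daily ETr24 series is missing days: {missing}")

    total = np.zeros_like(stack[0])
    doys_arr = np.asarray(doys, dtype=float)
    for day in days:
        j = int(np.searchsorted(doys_arr, day, side="right"))
        if j == 0:
            etrf_day = stack[0]
        elif j == len(doys_arr):
            etrf_day = stack[-1]
        else:
            d0, d1 = doys_arr[j - 1], doys_arr[j]
            w = (day - d0) / (d1 - d0)
            etrf_day = (1.0 - w) * stack[j - 1] + w * stack[j]
        total = total + etrf_day * etr24_by_doy[day]
    return total
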