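"""Vegetation indices, leaf area index, and surface emissivities.

The retrieval chain is the standard METRIC one: soil-adjusted vegetation index
(SAVI) from red/NIR at-surface reflectance, LAI from SAVI through an empirical
log relation capped at 6 m2 m-2, and narrowband/broadband emissivities as
piecewise-linear functions of LAI with an NDVI <= 0 water/snow branch.

Band roles (Landsat 7 bands 3/4 vs Landsat 8 bands 4/5) are resolved at ingest;
every function here is band-agnostic and operates on co-registered 2-D arrays
with NaN as missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rasters import Grid, check_same_shape

log = logging.getLogger(__name__)

@dataclass
class Scene:
    """One overpass: co-registered at-surface reflectance bands, at-sensor
    thermal radiance, and broadband albedo, with acquisition metadata.

    Band roles (red/NIR) are resolved from the sensor's band numbering at
    ingest, so everything downstream is band-agnostic. The thermal band is
    resampled to the reflectance grid before a Scene is built. NaN marks
    missing data in every band.
    """

    sensor: str  # "L7" | "L8"
    acquisition_doy: int
    red: np.ndarray
    nir: np.ndarray
    thermal_radiance: np.ndarray
    albedo: np.ndarray
    grid: Grid
    overpass_time: str = "11:12"

    def __post_init__(self):
        check_same_shape(self.red, self.nir, self.thermal_radiance, self.albedo)
        if self.red.shape != self.grid.shape:
            raise ValueError(f"band shape {self.red.shape} != grid {self.grid.shape}")
        for name in ("red", "nir", "albedo"):
            band = getattr(self, name)
            ok = np.isfinite(band)
            if np.any((band[ok] < 0) | (band[ok] > 1)):
                raise ValueError(f"{name} reflectance outside [0, 1]")
        tb = self.thermal_radiance
        if np.any(tb[np.isfinite(tb)] <= 0):
            raise ValueError("thermal radiance must be positive where valid")


#: soil-adjustment factor L of the SAVI formula
SAVI_L = 0.1
#: LAI ceiling applied by the model
LAI_CAP = 6.0

# LAI = -ln((A - SAVI)/B) / C, inverted by savi_from_lai
_LAI_A, _LAI_B, _LAI_C = 0.69, 0.59, 0.91


def compute_savi(nir: np.ndarray, red: np.ndarray, L: float = SAVI_L) -> np.ndarray:
    """SAVI = (1+L)(NIR-Red)/(L+NIR+Red); pixels with a vanishing denominator
    are masked (NaN), not raised."""
    if L < 0:
        raise ValueError(f"soil factor L must be >= 0, got {L}")
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    check_same_shape(nir, red)
    denom = L + nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        savi = np.where(np.abs(denom) > 1e-6, (1.0 + L) * (nir - red) / denom, np.nan)
    return savi


def compute_ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index, masked where NIR+Red ~ 0."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    check_same_shape(nir, red)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(np.abs(denom) > 1e-6, (nir - red) / denom, np.nan)
    return ndvi


def compute_lai(savi: np.ndarray) -> np.ndarray:
    """LAI = -ln((0.69 - SAVI)/0.59)/0.91, clamped to [0, 6].

    SAVI high enough that the raw value reaches 6 (or the logarithm is
    undefined) maps to exactly 6; SAVI <= 0.10, where the raw value is
    negative, maps to 0 — bare soil is valid scene content, not missing data.
    """
    savi = np.asarray(savi, dtype=float)
    arg = (_LAI_A - savi) / _LAI_B
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = -np.log(np.where(arg > 0, arg, np.nan)) / _LAI_C
    lai = np.where(np.isfinite(savi) & ~(arg > 0), LAI_CAP, raw)
    n_hi = int(np.sum(lai > LAI_CAP))
    n_lo = int(np.sum(lai < 0.0))
    if n_hi or n_lo:
        log.info("compute_lai: clamped %d pixels to %.0f and %d pixels to 0", n_hi, LAI_CAP, n_lo)
    return np.clip(lai, 0.0, LAI_CAP)


def savi_from_lai(lai: np.ndarray) -> np.ndarray:
    """Algebraic inverse of :func:`compute_lai` below the cap:
    SAVI = 0.69 - 0.59 exp(-0.91 LAI). Used by the synthetic forward model."""
    lai = np.asarray(lai, dtype=float)
    return _LAI_A - _LAI_B * np.exp(-_LAI_C * lai)


#: surface classification codes carried with the emissivity pair
CLASS_VEGETATED = 0
CLASS_WATER = 1
CLASS_SNOW = 2


@dataclass
class EmissivityPair:
    """Narrowband (thermal-sensor band) and broadband emissivity rasters, plus
    a classification tag (vegetated/soil, water, snow) kept for reporting."""

    eps_nb: np.ndarray
    eps_0: np.ndarray
    surface_class: np.ndarray


def compute_emissivities(lai: np.ndarray, ndvi: np.ndarray, albedo: np.ndarray) -> EmissivityPair:
    """Piecewise emissivity model.

    NDVI > 0, LAI <= 3:  eps_nb = 0.97 + 0.0033 LAI,  eps_0 = 0.95 + 0.01 LAI
    NDVI > 0, LAI > 3:   eps_nb = eps_0 = 0.98
    NDVI <= 0:           eps_nb = 0.99, eps_0 = 0.985 (water when albedo < 0.47,
                         snow otherwise; the two branches share values and are
                         distinguished only by the classification tag)
    """
    lai = np.asarray(lai, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    albedo = np.asarray(albedo, dtype=float)
    check_same_shape(lai, ndvi, albedo)

    eps_nb = np.where(lai <= 3.0, 0.97 + 0.0033 * lai, 0.98)
    eps_0 = np.where(lai <= 3.0, 0.95 + 0.01 * lai, 0.98)
    non_veg = ndvi <= 0
    eps_nb = np.where(non_veg, 0.99, eps_nb)
    eps_0 = np.where(non_veg, 0.985, eps_0)

    surface_class = np.full(lai.shape, CLASS_VEGETATED, dtype=np.int8)
    surface_class[non_veg & (albedo < 0.47)] = CLASS_WATER
    surface_class[non_veg & (albedo >= 0.47)] = CLASS_SNOW

    invalid = ~np.isfinite(lai) | ~np.isfinite(ndvi)
    eps_nb = np.where(invalid, np.nan, eps_nb)
    eps_0 = np.where(invalid, np.nan, eps_0)
    return EmissivityPair(eps_nb=eps_nb, eps_0=eps_0, surface_class=surface_class)
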