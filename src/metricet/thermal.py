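"""Thermal-band radiance to radiometric surface temperature.

Implements the modified-Planck inversion Ts = K2 / ln(eps_nb K1 / Rc + 1) with
per-sensor calibration constants, an optional atmospheric correction of the
at-sensor radiance, the exact forward model (radiance from temperature) used by
the synthetic scene generator, and the latent heat of vaporization as a
function of surface temperature.

All temperatures are kelvin internally; convert to Celsius only at reporting
boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThermalConstants:
    """Planck-inversion calibration constants for one thermal band."""

    k1: float  # W m-2 sr-1 um-1
    k2: float  # K

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError(f"thermal constants must be positive, got {self}")


#: Default constants per sensor. The Landsat 8 pair is kept as published in the
#: source material, labelled Band 10 there although the values match the
#: published Band 11 constants; override via ThermalConstants in the run config
#: if the true Band 10 pair (774.89 / 1321.08) is wanted.
SENSOR_CONSTANTS: dict[str, ThermalConstants] = {
    "L7": ThermalConstants(k1=666.1, k2=1282.7),
    "L8": ThermalConstants(k1=480.9, k2=1201.1),
}


def constants_for(sensor: str) -> ThermalConstants:
    try:
        constants = SENSOR_CONSTANTS[sensor]
    except KeyError:
        raise ValueError(f"unknown sensor {sensor!r}; expected one of {sorted(SENSOR_CONSTANTS)}")
    if sensor == "L8":
        log.warning(
            "Landsat 8 thermal constants K1=480.9/K2=1201.1 (labelled Band 10 in the "
            "source) match the published Band 11 pair; override in config if needed."
        )
    return constants


@dataclass(frozen=True)
class AtmosphericCorrection:
    """Narrowband atmospheric correction of at-sensor thermal radiance.

    Defaults (tau=1, Rp=0, Rsky=0) reduce the correction to the identity, i.e.
    at-sensor radiance is taken as surface-leaving radiance.
    """

    tau_nb: float = 1.0
    path_radiance: float = 0.0  # Rp, W m-2 sr-1 um-1
    sky_radiance: float = 0.0  # Rsky, W m-2 sr-1 um-1

    def __post_init__(self):
        if not (0.0 < self.tau_nb <= 1.0):
            raise ValueError(f"tau_nb must be in (0, 1], got {self.tau_nb}")


def correct_thermal_radiance(
    sensor_radiance: np.ndarray,
    eps_nb: np.ndarray,
    corr: AtmosphericCorrection = AtmosphericCorrection(),
) -> np.ndarray:
    """Rc = (L_sensor - Rp)/tau_nb - (1 - eps_nb) Rsky."""
    sensor_radiance = np.asarray(sensor_radiance, dtype=float)
    eps_nb = np.asarray(eps_nb, dtype=float)
    return (sensor_radiance - corr.path_radiance) / corr.tau_nb - (1.0 - eps_nb) * corr.sky_radiance


def surface_temperature(
    rc: np.ndarray, eps_nb: np.ndarray, constants: ThermalConstants
) -> np.ndarray:
    """Ts = K2 / ln(eps_nb K1 / Rc + 1), kelvin; Rc <= 0 pixels are masked."""
    rc = np.asarray(rc, dtype=float)
    eps_nb = np.asarray(eps_nb, dtype=float)
    bad = ~(rc > 0)
    n_bad = int(np.sum(bad & np.isfinite(rc)))
    if n_bad:
        log.info("surface_temperature: masked %d pixels with non-positive radiance", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        ts = constants.k2 / np.log(eps_nb * constants.k1 / np.where(bad, np.nan, rc) + 1.0)
    return ts


def radiance_from_temperature(
    ts: np.ndarray, eps_nb: np.ndarray, constants: ThermalConstants
) -> np.ndarray:
    """Exact inverse of :func:`surface_temperature`:
    Rc = eps_nb K1 / (exp(K2/Ts) - 1)."""
    ts = np.asarray(ts, dtype=float)
    if np.any(ts[np.isfinite(ts)] <= 0):
        raise ValueError("temperature must be positive kelvin")
    eps_nb = np.asarray(eps_nb, dtype=float)
    return eps_nb * constants.k1 / (np.exp(constants.k2 / ts) - 1.0)


def latent_heat_of_vaporization(ts: np.ndarray) -> np.ndarray:
    """lambda = (2.501 - 0.00236 (Ts - 273.15)) 1e6, J kg-1, Ts in kelvin."""
    ts = np.asarray(ts, dtype=float)
    return (2.501 - 0.00236 * (ts - 273.15)) * 1.0e6
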