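"""Surface energy balance: net radiation, soil heat flux, CIMEC-calibrated
sensible heat flux, and latent heat flux by residual.

The sensible-heat scheme is the internalized-calibration one: the near-surface
temperature difference dT (between z1 = 0.1 m and z2 = 2 m) is taken linear in
radiometric surface temperature, dT = a + b Ts, with (a, b) fitted so that a
"cold" anchor pixel (well-watered, full-cover vegetation) evaporates at a fixed
fraction of alfalfa-reference ET (default 1.05) and a "hot" anchor pixel (dry
bare soil) at 0. H = rho_air Cp dT / rah per pixel, with aerodynamic resistance
rah from a neutral log profile optionally refined by Monin-Obukhov stability
corrections; the (a, b) fit and the resistances are iterated jointly to
convergence. LE = Rn - G - H closes the balance exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .rasters import check_same_shape
from .thermal import latent_heat_of_vaporization

log = logging.getLogger(__name__)

STEFAN_BOLTZMANN = 5.670e-8  # W m-2 K-4
CP_AIR = 1004.0  # J kg-1 K-1
VON_KARMAN = 0.41
GRAVITY = 9.81  # m s-2
Z1 = 0.1  # m, lower dT height
Z2 = 2.0  # m, upper dT height
BLENDING_HEIGHT = 200.0  # m
RHO_AIR_DEFAULT = 1.15  # kg m-3, used when no pressure/temperature available


# ---------------------------------------------------------------------------
# radiation and soil heat flux


@dataclass(frozen=True)
class RadiationInputs:
    """Station shortwave/longwave forcing for the net-radiation assembly.

    ``rl_down=None`` requests the clear-sky emissivity parameterization
    eps_a = 0.85 (-ln tau_sw)^0.09 with tau_sw = 0.75 + 2e-5 elevation.
    """

    rs_down: float  # W m-2
    air_temp: float  # K
    elevation: float = 0.0  # m
    rl_down: float | None = None  # W m-2

    def __post_init__(self):
        if self.rs_down < 0:
            raise ValueError(f"rs_down must be >= 0, got {self.rs_down}")
        if self.rl_down is not None and self.rl_down <= 0:
            raise ValueError(f"rl_down must be > 0 when supplied, got {self.rl_down}")


def incoming_longwave(air_temp: float, elevation: float) -> float:
    """Clear-sky RL_down = eps_a sigma Ta^4 with the broadband transmissivity
    parameterization above."""
    tau_sw = 0.75 + 2e-5 * elevation
    eps_a = 0.85 * (-np.log(tau_sw)) ** 0.09
    return float(eps_a * STEFAN_BOLTZMANN * air_temp**4)


def net_radiation(
    albedo: np.ndarray, ts: np.ndarray, eps_0: np.ndarray, rad: RadiationInputs
) -> np.ndarray:
    """Rn = RS_down - alpha RS_down + RL_down - RL_up - (1 - eps_0) RL_down,
    with RL_up = eps_0 sigma Ts^4."""
    albedo = np.asarray(albedo, dtype=float)
    ts = np.asarray(ts, dtype=float)
    eps_0 = np.asarray(eps_0, dtype=float)
    check_same_shape(albedo, ts, eps_0)
    rl_down = rad.rl_down if rad.rl_down is not None else incoming_longwave(rad.air_temp, rad.elevation)
    rl_up = eps_0 * STEFAN_BOLTZMANN * ts**4
    return rad.rs_down - albedo * rad.rs_down + rl_down - rl_up - (1.0 - eps_0) * rl_down


def soil_heat_flux(rn: np.ndarray, lai: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """G from the two-branch LAI parameterization:

    G/Rn = 0.05 + 0.18 exp(-0.521 LAI)            for LAI >= 0.5
    G/Rn = 1.80 (Ts - 273.16)/Rn + 0.084           for LAI < 0.5

    Ts in kelvin. Pixels with Rn = 0 on the sparse branch are masked.
    """
    rn = np.asarray(rn, dtype=float)
    lai = np.asarray(lai, dtype=float)
    ts = np.asarray(ts, dtype=float)
    check_same_shape(rn, lai, ts)
    dense = rn * (0.05 + 0.18 * np.exp(-0.521 * lai))
    with np.errstate(invalid="ignore", divide="ignore"):
        sparse_ratio = np.where(rn != 0, 1.80 * (ts - 273.16) / rn + 0.084, np.nan)
    n_masked = int(np.sum((lai < 0.5) & (rn == 0)))
    if n_masked:
        log.info("soil_heat_flux: masked %d sparse-canopy pixels with Rn=0", n_masked)
    return np.where(lai >= 0.5, dense, sparse_ratio * rn)


# ---------------------------------------------------------------------------
# aerodynamics


@dataclass
class AerodynamicState:
    """Per-pixel aerodynamic quantities plus the scalar station context."""

    rho_air: float  # kg m-3
    wind_speed: float  # m s-1 at the station anemometer
    u200: float  # m s-1 at blending height
    zom: np.ndarray  # m, momentum roughness length
    u_star: np.ndarray  # m s-1
    rah: np.ndarray  # s m-1, aerodynamic resistance z1->z2
    cp: float = CP_AIR
    z1: float = Z1
    z2: float = Z2
    blending_height: float = BLENDING_HEIGHT


def air_density(air_temp: float | None = None, elevation: float | None = None) -> float:
    """Ideal-gas air density at station pressure
    P = 101.3 ((293 - 0.0065 z)/293)^5.26 kPa; falls back to 1.15 kg m-3 when
    temperature or elevation is unknown."""
    if air_temp is None or elevation is None:
        return RHO_AIR_DEFAULT
    p_kpa = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    return float(1000.0 * p_kpa / (287.0 * air_temp))


def aerodynamic_state(
    wind_speed: float,
    station_zom: float,
    lai: np.ndarray,
    anemometer_height: float = 2.0,
    rho_air: float = RHO_AIR_DEFAULT,
) -> AerodynamicState:
    """Neutral-stability initial aerodynamics.

    zom = max(0.018 LAI, 0.005) m; wind is lifted from the anemometer to the
    200 m blending height over the station roughness, then brought down over
    each pixel's roughness: u* = k u200 / ln(200/zom);
    rah = ln(z2/z1)/(u* k).
    """
    if wind_speed <= 0:
        raise ValueError(f"wind_speed must be > 0, got {wind_speed}")
    lai = np.asarray(lai, dtype=float)
    zom = np.maximum(0.018 * lai, 0.005)
    u200 = wind_speed * np.log(BLENDING_HEIGHT / station_zom) / np.log(anemometer_height / station_zom)
    u_star = VON_KARMAN * u200 / np.log(BLENDING_HEIGHT / zom)
    rah = np.log(Z2 / Z1) / (u_star * VON_KARMAN)
    return AerodynamicState(
        rho_air=rho_air, wind_speed=wind_speed, u200=float(u200),
        zom=zom, u_star=u_star, rah=rah,
    )


# ---------------------------------------------------------------------------
# CIMEC calibration


@dataclass
class CalibrationAnchors:
    """Hot/cold anchor pixels and the fitted dT-vs-Ts line."""

    cold_index: tuple[int, int]
    hot_index: tuple[int, int]
    etrf_cold: float = 1.05
    etrf_hot: float = 0.0
    a: float | None = None  # K
    b: float | None = None  # K K-1
    iterations: int = 0
    converged: bool = False


def select_calibration_pixels(
    ts: np.ndarray,
    lai: np.ndarray,
    ndvi: np.ndarray,
    manual: tuple[tuple[int, int], tuple[int, int]] | None = None,
    etrf_cold: float = 1.05,
    etrf_hot: float = 0.0,
) -> CalibrationAnchors:
    """Automatic anchor choice: cold = coolest pixel among the top-5% NDVI,
    hot = warmest pixel among the bottom-10% NDVI; ties broken by row-major
    order. ``manual`` coordinates override the search verbatim."""
    if manual is not None:
        return CalibrationAnchors(cold_index=tuple(manual[0]), hot_index=tuple(manual[1]),
                                  etrf_cold=etrf_cold, etrf_hot=etrf_hot)
    ts = np.asarray(ts, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    check_same_shape(ts, lai, ndvi)
    ok = np.isfinite(ts) & np.isfinite(ndvi)
    if int(ok.sum()) < 100:
        raise ValueError("anchor selection needs >= 100 unmasked pixels; supply manual anchors")
    ndvi_ok = ndvi[ok]
    hi, lo = np.quantile(ndvi_ok, 0.95), np.quantile(ndvi_ok, 0.10)
    cold_cand = ok & (ndvi >= hi)
    hot_cand = ok & (ndvi <= lo)
    if not cold_cand.any() or not hot_cand.any():
        raise ValueError("empty anchor candidate set; supply manual anchors")
    ts_cold = np.where(cold_cand, ts, np.inf)
    ts_hot = np.where(hot_cand, ts, -np.inf)
    cold_index = np.unravel_index(int(np.argmin(ts_cold)), ts.shape)
    hot_index = np.unravel_index(int(np.argmax(ts_hot)), ts.shape)
    return CalibrationAnchors(cold_index=tuple(map(int, cold_index)),
                              hot_index=tuple(map(int, hot_index)),
                              etrf_cold=etrf_cold, etrf_hot=etrf_hot)


def calibrate_dT(
    rn: np.ndarray,
    g: np.ndarray,
    ts: np.ndarray,
    anchors: CalibrationAnchors,
    aero: AerodynamicState,
    etr_inst: float,
) -> CalibrationAnchors:
    """Single-pass inverse-modelling fit of the dT line.

    At each anchor, LE = ETrF_anchor * ETr_inst * lambda(Ts) / 3600 (ETr in
    mm h-1, i.e. kg m-2 h-1), H = Rn - G - LE, dT = H rah / (rho_air Cp); the
    line (a, b) interpolates the two (Ts, dT) points.
    """
    if etr_inst <= 0:
        raise ValueError(f"etr_inst must be > 0, got {etr_inst}")
    ci, hi_ = anchors.cold_index, anchors.hot_index
    ts_cold, ts_hot = float(ts[ci]), float(ts[hi_])
    if not np.isfinite(ts_cold) or not np.isfinite(ts_hot):
        raise ValueError("anchor pixels are masked")
    if ts_hot <= ts_cold:
        raise ValueError(f"degenerate anchors: Ts(hot)={ts_hot:.2f} <= Ts(cold)={ts_cold:.2f} K")
    rho_cp = aero.rho_air * aero.cp
    dT = {}
    for idx, etrf in ((ci, anchors.etrf_cold), (hi_, anchors.etrf_hot)):
        le = etrf * etr_inst * float(latent_heat_of_vaporization(ts[idx])) / 3600.0
        h = float(rn[idx]) - float(g[idx]) - le
        dT[idx] = h * float(aero.rah[idx]) / rho_cp
    b = (dT[hi_] - dT[ci]) / (ts_hot - ts_cold)
    a = dT[ci] - b * ts_cold
    return replace(anchors, a=float(a), b=float(b))


def sensible_heat_flux(ts: np.ndarray, anchors: CalibrationAnchors, aero: AerodynamicState) -> np.ndarray:
    """H = rho_air Cp (a + b Ts) / rah with the calibrated dT line."""
    if anchors.a is None or anchors.b is None:
        raise ValueError("anchors are not calibrated (a, b missing); run calibrate_dT first")
    ts = np.asarray(ts, dtype=float)
    dT = anchors.a + anchors.b * ts
    return aero.rho_air * aero.cp * dT / aero.rah


# Monin-Obukhov stability functions -----------------------------------------


def _psi_terms(length: np.ndarray, z: float, momentum_at_blending: bool):
    """Integrated stability correction psi at height z for Obukhov length L.
    Neutral limit |L| -> inf gives 0. ``momentum_at_blending`` selects the
    momentum form evaluated at the 200 m blending height."""
    length = np.asarray(length, dtype=float)
    psi = np.zeros_like(length)
    unstable = length < 0
    stable = length > 0
    with np.errstate(invalid="ignore"):
        x = np.where(unstable, (1.0 - 16.0 * z / np.where(unstable, length, -1.0)) ** 0.25, 1.0)
    if momentum_at_blending:
        psi_u = (2.0 * np.log((1.0 + x) / 2.0) + np.log((1.0 + x**2) / 2.0)
                 - 2.0 * np.arctan(x) + np.pi / 2.0)
    else:
        psi_u = 2.0 * np.log((1.0 + x**2) / 2.0)
    psi[unstable] = psi_u[unstable]
    # stable branch: -5 z/L with z/L capped at 1 (strongly-stable limit), else
    # weak-wind anchors drive rah to the clamp and the dT line runs away
    psi[stable] = -5.0 * np.minimum(z / length, 1.0)[stable]
    return psi


def solve_sensible_heat(
    rn: np.ndarray,
    g: np.ndarray,
    ts: np.ndarray,
    anchors: CalibrationAnchors,
    aero: AerodynamicState,
    etr_inst: float,
    stability: bool = True,
    max_iter: int = 30,
    tol: float = 1e-3,
) -> tuple[np.ndarray, CalibrationAnchors, AerodynamicState]:
    """Jointly iterate the dT calibration and the stability-corrected
    aerodynamic resistances.

    Each pass refits (a, b) with the current anchor resistances, evaluates H,
    computes the Obukhov length L = -rho Cp u*^3 Ts / (k g H), updates u* and
    rah with the psi corrections, and repeats until the dT line moves by less
    than ``tol`` kelvin (max |da|, |db| Ts_hot) or ``max_iter`` passes. With
    ``stability=False`` a single neutral pass is performed.
    """
    ts = np.asarray(ts, dtype=float)
    ts_hot = float(ts[anchors.hot_index])
    prev_a = prev_b = None
    h = np.zeros_like(ts)
    for iteration in range(1, max_iter + 1):
        anchors = calibrate_dT(rn, g, ts, anchors, aero, etr_inst)
        h = sensible_heat_flux(ts, anchors, aero)
        if not stability:
            anchors = replace(anchors, iterations=iteration, converged=True)
            return h, anchors, aero
        if prev_a is not None:
            delta = max(abs(anchors.a - prev_a), abs(anchors.b - prev_b) * abs(ts_hot))
            log.debug("CIMEC pass %d: a=%.4f b=%.6f delta=%.2e", iteration, anchors.a, anchors.b, delta)
            if delta < tol:
                anchors = replace(anchors, iterations=iteration, converged=True)
                return h, anchors, aero
        prev_a, prev_b = anchors.a, anchors.b
        # Obukhov length; |H| ~ 0 pixels go to the neutral limit (psi = 0).
        rho_cp = aero.rho_air * aero.cp
        with np.errstate(divide="ignore", invalid="ignore"):
            length = np.where(
                np.abs(h) > 1e-6,
                -rho_cp * aero.u_star**3 * ts / (VON_KARMAN * GRAVITY * h),
                np.inf,
            )
        psi_m200 = _psi_terms(length, aero.blending_height, momentum_at_blending=True)
        psi_h2 = _psi_terms(length, aero.z2, momentum_at_blending=False)
        psi_h1 = _psi_terms(length, aero.z1, momentum_at_blending=False)
        denom = np.maximum(np.log(aero.blending_height / aero.zom) - psi_m200, 0.1)
        u_star = np.maximum(VON_KARMAN * aero.u200 / denom, 1e-3)
        rah = np.clip(
            (np.log(aero.z2 / aero.z1) - psi_h2 + psi_h1) / (u_star * VON_KARMAN), 1.0, 1000.0
        )
        # under-relax the resistance update: successive substitution oscillates
        # in strongly unstable low-wind conditions
        rah = 0.5 * rah + 0.5 * aero.rah
        aero = replace(aero, u_star=u_star, rah=rah)
    log.warning("CIMEC calibration did not converge in %d passes; returning last iterate", max_iter)
    return h, replace(anchors, iterations=max_iter, converged=False), aero


def close_balance(rn: np.ndarray, g: np.ndarray, h: np.ndarray) -> np.ndarray:
    """LE = Rn - G - H. Negative LE (advection, field edges) is permitted and
    counted; ET products clamp downstream."""
    rn = np.asarray(rn, dtype=float)
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    check_same_shape(rn, g, h)
    le = rn - g - h
    n_neg = int(np.sum(le < 0))
    if n_neg:
        log.info("close_balance: %d pixels with negative LE", n_neg)
    return le
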