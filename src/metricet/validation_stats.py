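"""Model vs in-situ agreement statistics and comparison-table assembly.

A comparison table is a DataFrame of paired observations with columns
``doy, location, estimated, measured`` (estimated = model, measured = ground).
Statistics follow the study conventions: r2 as the squared Pearson correlation,
mean bias error MBE = mean(estimated - measured) with its magnitude also
surfaced, paired RMSE, and the regression standard error of estimate
sqrt(Syy (1 - r2) / (n - ddof)) — the latter because published "RMSE" values
for scatterplot fits are often standard errors of the fitted line rather than
paired root-mean-square differences; both readings are first-class here.

The packaged fixture tables (LAI, surface temperature, daily ETa at five
observation locations over the 2016 corn season) load via ``load_fixture``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["doy", "location", "estimated", "measured"]

#: observation locations of the study field
LOCATIONS = ["S-E", "S", "N", "E", "E-E"]

_FIXTURES = {
    "lai": "table_lai_comparison.csv",
    "ts": "table_ts_comparison.csv",
    "eta": "table_eta_metric.csv",
}


def _validate(table: pd.DataFrame, min_n: int = 2) -> pd.DataFrame:
    missing = [c for c in ("estimated", "measured") if c not in table.columns]
    if missing:
        raise ValueError(f"comparison table is missing columns: {missing}")
    t = table.dropna(subset=["estimated", "measured"])
    if len(t) < min_n:
        raise ValueError(f"need at least {min_n} complete pairs, got {len(t)}")
    return t


def r_squared(table: pd.DataFrame) -> float:
    """Squared Pearson correlation of (estimated, measured); errors on zero
    variance in either column."""
    t = _validate(table)
    x, y = t["estimated"].to_numpy(float), t["measured"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r_squared undefined: zero variance in a column")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def mbe(table: pd.DataFrame) -> float:
    """Signed mean bias error, mean(estimated - measured)."""
    t = _validate(table, min_n=1)
    return float(np.mean(t["estimated"].to_numpy(float) - t["measured"].to_numpy(float)))


def rmse(table: pd.DataFrame) -> float:
    """Paired root-mean-square error sqrt(mean((estimated - measured)^2))."""
    t = _validate(table, min_n=1)
    d = t["estimated"].to_numpy(float) - t["measured"].to_numpy(float)
    return float(np.sqrt(np.mean(d * d)))


def regression_se(table: pd.DataFrame, ddof: int = 1) -> float:
    """Standard error of estimate of the least-squares fit of measured on
    estimated: sqrt(Syy (1 - r2) / (n - ddof))."""
    t = _validate(table)
    n = len(t)
    if not (0 <= ddof < n):
        raise ValueError(f"need n > ddof >= 0, got n={n}, ddof={ddof}")
    y = t["measured"].to_numpy(float)
    syy = float(np.sum((y - y.mean()) ** 2))
    return float(np.sqrt(syy * (1.0 - r_squared(t)) / (n - ddof)))


def summarize(table: pd.DataFrame, variable: str = "", units: str = "") -> dict:
    """One-row stats report: n, r2, MBE, |MBE|, paired RMSE, regression SE."""
    t = _validate(table)
    return {
        "variable": variable,
        "units": units,
        "n": len(t),
        "r2": r_squared(t),
        "mbe": mbe(t),
        "mbe_abs": abs(mbe(t)),
        "rmse": rmse(t),
        "se_regression": regression_se(t, ddof=1),
    }


def block_mean(raster: np.ndarray, row: int, col: int, size: int = 3) -> tuple[float, bool]:
    """Mean of the size x size pixel block centred on (row, col); blocks
    overlapping the raster edge or masked pixels yield a partial mean with a
    flag. Errors when the centre lies outside the raster."""
    raster = np.asarray(raster, dtype=float)
    nr, nc = raster.shape
    if not (0 <= row < nr and 0 <= col < nc):
        raise IndexError(f"site pixel ({row}, {col}) outside raster {raster.shape}")
    half = size // 2
    block = raster[max(row - half, 0): row + half + 1, max(col - half, 0): col + half + 1]
    n_valid = int(np.isfinite(block).sum())
    partial = n_valid < size * size
    if n_valid == 0:
        return float("nan"), True
    return float(np.nanmean(block)), partial


def build_comparison(
    rasters_by_doy: dict[int, np.ndarray],
    sites: dict[str, tuple[int, int]],
    measurements: pd.DataFrame,
    variable: str = "",
) -> pd.DataFrame:
    """Pair per-site model samples with in-situ measurements.

    The model value at a site is the mean of the nine pixels (3x3 block)
    centred on the site pixel. ``measurements`` needs columns
    ``doy, location, measured``. Rows without a matching raster or site are
    dropped; partial blocks are flagged in a ``partial_block`` column.
    """
    rows = []
    for _, m in measurements.iterrows():
        doy, loc = int(m["doy"]), m["location"]
        if doy not in rasters_by_doy or loc not in sites:
            continue
        r, c = sites[loc]
        value, partial = block_mean(rasters_by_doy[doy], r, c)
        rows.append({"doy": doy, "location": loc, "estimated": value,
                     "measured": float(m["measured"]), "partial_block": partial})
    table = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + ["partial_block"])
    table.attrs["variable"] = variable
    return table


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged study table: ``"lai"`` (model vs ceptometer LAI pairs),
    ``"ts"`` (model vs infrared-thermometer surface temperature pairs), or
    ``"eta"`` (model daily ETa per location and overpass date)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}")
    with resources.files("metricet.data").joinpath(_FIXTURES[name]).open() as fh:
        return pd.read_csv(fh)
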