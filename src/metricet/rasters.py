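"""Lightweight raster containers and TIFF I/O.

Bands are plain 2-D float64 :class:`numpy.ndarray` with NaN as the in-memory
missing-data marker; every operation in the pipeline propagates NaN. On disk a
band is a float32 TIFF with nodata -9999 plus a small JSON sidecar
(``<name>.grid.json``) holding the grid: pixel size, map origin, north-up
orientation. The sidecar stands in for full geo-tags so round trips preserve
georeferencing without a GDAL dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile

NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Regular north-up grid. Origin is the map coordinate of the upper-left
    corner of pixel (0, 0); rows increase southwards."""

    rows: int
    cols: int
    pixel_size: float = 30.0
    x_origin: float = 0.0
    y_origin: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)


def check_same_shape(*bands: np.ndarray) -> None:
    """Raise ``ValueError`` unless all bands share one 2-D shape."""
    shapes = {np.asarray(b).shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"bands are not co-registered: shapes {sorted(shapes)}")


def valid_mask(*bands: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels finite in every band."""
    check_same_shape(*bands)
    mask = np.ones(np.asarray(bands[0]).shape, dtype=bool)
    for b in bands:
        mask &= np.isfinite(np.asarray(b, dtype=float))
    return mask


def write_band(path: str | Path, data: np.ndarray, grid: Grid, nodata: float = NODATA) -> Path:
    path = Path(path)
    out = np.asarray(data, dtype=np.float32).copy()
    out[~np.isfinite(out)] = nodata
    tifffile.imwrite(path, out)
    sidecar = {"nodata": nodata, **asdict(grid)}
    path.with_suffix(path.suffix + ".grid.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_band(path: str | Path) -> tuple[np.ndarray, Grid]:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sidecar_path = path.with_suffix(path.suffix + ".grid.json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        nodata = meta.pop("nodata", NODATA)
        grid = Grid(**meta)
    else:
        nodata = NODATA
        grid = Grid(rows=data.shape[0], cols=data.shape[1])
    if data.shape != grid.shape:
        raise ValueError(f"{path}: data shape {data.shape} != sidecar grid {grid.shape}")
    data[data == nodata] = np.nan
    return data, grid


def resample_nearest(data: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resampling of a coarse band onto a finer grid sharing
    the same extent (e.g. 60 m / 100 m thermal onto the 30 m reflectance grid)."""
    data = np.asarray(data, dtype=float)
    rows, cols = target_shape
    r_idx = np.minimum((np.arange(rows) * data.shape[0] / rows).astype(int), data.shape[0] - 1)
    c_idx = np.minimum((np.arange(cols) * data.shape[1] / cols).astype(int), data.shape[1] - 1)
    return data[np.ix_(r_idx, c_idx)]
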