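"""Season run-directory layout: write synthetic seasons, read scenes back.

A season directory holds a ``season.json`` manifest (grid, overpass dates and
sensors, site pixels, station metadata), a ``weather.csv`` table, per-variable
in-situ tables ``insitu_<var>.csv``, and one band directory per overpass with
float32 TIFF bands (red, nir, thermal, albedo) plus grid sidecars. Truth
rasters from the generator are written alongside under ``truth_doy<ddd>/``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import synthetic_scenes as syn
from .radiometry import Scene
from .rasters import Grid, read_band, write_band

BANDS = ("red", "nir", "thermal", "albedo")


def write_season_dir(cfg: syn.SeasonConfig, outdir: str | Path) -> Path:
    """Materialize a full synthetic season (scenes, truth, weather, in-situ)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenes, truths, weather = syn.generate_season(cfg)
    insitu = syn.generate_ground_truth(cfg, truths)

    manifest = {
        "overpass_doys": list(cfg.overpass_doys),
        "sensors": {str(s.acquisition_doy): s.sensor for s in scenes},
        "sites": {s.name: [s.row, s.col] for s in cfg.sites},
        "grid": asdict(cfg.grid),
        "elevation": cfg.elevation,
        "station_zom": cfg.station_zom,
        "seed": cfg.seed,
    }
    (outdir / "season.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    weather.to_csv(outdir / "weather.csv", index=False)
    for variable, table in insitu.items():
        table.to_csv(outdir / f"insitu_{variable}.csv", index=False)

    for scene, truth in zip(scenes, truths):
        scene_dir = outdir / f"scene_doy{scene.acquisition_doy:03d}"
        scene_dir.mkdir(exist_ok=True)
        arrays = {"red": scene.red, "nir": scene.nir,
                  "thermal": scene.thermal_radiance, "albedo": scene.albedo}
        for band, data in arrays.items():
            write_band(scene_dir / f"{band}.tif", data, scene.grid)
        truth_dir = outdir / f"truth_doy{scene.acquisition_doy:03d}"
        truth_dir.mkdir(exist_ok=True)
        for name, data in (("lai", truth.lai), ("ts", truth.ts),
                           ("etrf", truth.etrf), ("eta", truth.eta)):
            write_band(truth_dir / f"{name}.tif", data, scene.grid)
    return outdir


def read_manifest(season_dir: str | Path) -> dict:
    path = Path(season_dir) / "season.json"
    if not path.exists():
        raise FileNotFoundError(f"no season manifest at {path}")
    return json.loads(path.read_text())


def load_scene(season_dir: str | Path, doy: int) -> Scene:
    """Read one overpass's bands back into a Scene."""
    season_dir = Path(season_dir)
    manifest = read_manifest(season_dir)
    scene_dir = season_dir / f"scene_doy{doy:03d}"
    arrays, grids = {}, []
    for band in BANDS:
        path = scene_dir / f"{band}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing {band} band: {path}")
        arrays[band], grid = read_band(path)
        grids.append(grid)
    if len({g.shape for g in grids}) != 1:
        raise ValueError(f"bands in {scene_dir} are not co-registered")
    sensor = manifest["sensors"].get(str(doy), "L8")
    return Scene(sensor=sensor, acquisition_doy=int(doy), red=arrays["red"],
                 nir=arrays["nir"], thermal_radiance=arrays["thermal"],
                 albedo=arrays["albedo"], grid=grids[0])


def load_weather(season_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(season_dir) / "weather.csv")


def load_insitu(season_dir: str | Path) -> dict[str, pd.DataFrame]:
    out = {}
    for variable in ("lai", "ts", "eta"):
        path = Path(season_dir) / f"insitu_{variable}.csv"
        if path.exists():
            out[variable] = pd.read_csv(path)
    return out


def site_pixels(season_dir: str | Path) -> dict[str, tuple[int, int]]:
    manifest = read_manifest(season_dir)
    return {name: (int(rc[0]), int(rc[1])) for name, rc in manifest["sites"].items()}


def grid_from_manifest(season_dir: str | Path) -> Grid:
    return Grid(**read_manifest(season_dir)["grid"])
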