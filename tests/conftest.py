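import logging

import pytest

from metricet import pipeline as pl
from metricet import synthetic_scenes as syn

logging.getLogger("metricet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def zero_noise_cfg() -> syn.SeasonConfig:
    return syn.SeasonConfig(seed=11).zero_noise()


@pytest.fixture(scope="session")
def zero_noise_season(zero_noise_cfg):
    """Full zero-noise synthetic season processed with neutral stability (the
    forward model's regime), shared across round-trip tests."""
    scenes, truths, weather = syn.generate_season(zero_noise_cfg)
    params = pl.ProcessParams(elevation=zero_noise_cfg.elevation,
                              station_zom=zero_noise_cfg.station_zom,
                              stability=False)
    results = []
    for scene in scenes:
        row = weather.loc[weather["doy"] == scene.acquisition_doy].iloc[0]
        results.append(pl.process_scene(scene, row, params))
    return zero_noise_cfg, scenes, truths, weather, results


@pytest.fixture(scope="session")
def noisy_season():
    """Default-noise season processed with the full stability iteration."""
    cfg = syn.SeasonConfig(seed=5)
    scenes, truths, weather = syn.generate_season(cfg)
    params = pl.ProcessParams(elevation=cfg.elevation, station_zom=cfg.station_zom)
    results = []
    for scene in scenes:
        row = weather.loc[weather["doy"] == scene.acquisition_doy].iloc[0]
        results.append(pl.process_scene(scene, row, params))
    return cfg, scenes, truths, weather, results
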