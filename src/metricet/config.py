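"""Run configuration: a single YAML file validated on load.

Every violation is reported at once (not first-error-wins), and a resolved
copy of the configuration is written next to the outputs for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .pipeline import ProcessParams
from .thermal import AtmosphericCorrection, ThermalConstants


@dataclass
class RunConfig:
    """Validated settings for the command-line pipeline."""

    season_dir: str = "."
    output_dir: str = "outputs"
    elevation: float = 495.0
    station_zom: float = 0.03
    anemometer_height: float = 2.0
    etrf_cold: float = 1.05
    etrf_hot: float = 0.0
    stability: bool = True
    max_iterations: int = 30
    manual_anchors: list | None = None  # [[row, col], [row, col]]
    thermal_k1: float | None = None  # override; default per sensor
    thermal_k2: float | None = None
    tau_nb: float = 1.0
    path_radiance: float = 0.0
    sky_radiance: float = 0.0
    seed: int = 0
    log_level: str = "INFO"
    kc_knots: list = field(default_factory=list)  # [[dae, kc], ...]

    def validate(self) -> None:
        problems = []
        if self.station_zom <= 0:
            problems.append(f"station_zom must be > 0, got {self.station_zom}")
        if self.anemometer_height <= 0:
            problems.append(f"anemometer_height must be > 0, got {self.anemometer_height}")
        if not (0 < self.tau_nb <= 1):
            problems.append(f"tau_nb must be in (0, 1], got {self.tau_nb}")
        if self.etrf_cold <= self.etrf_hot:
            problems.append(f"etrf_cold ({self.etrf_cold}) must exceed etrf_hot ({self.etrf_hot})")
        if self.max_iterations < 1:
            problems.append(f"max_iterations must be >= 1, got {self.max_iterations}")
        if (self.thermal_k1 is None) != (self.thermal_k2 is None):
            problems.append("thermal_k1 and thermal_k2 must be overridden together")
        if self.manual_anchors is not None:
            ok = (isinstance(self.manual_anchors, (list, tuple)) and len(self.manual_anchors) == 2
                  and all(len(p) == 2 for p in self.manual_anchors))
            if not ok:
                problems.append(f"manual_anchors must be [[row, col], [row, col]], got {self.manual_anchors}")
        if problems:
            raise ValueError("invalid run config:\n  - " + "\n  - ".join(problems))

    def process_params(self) -> ProcessParams:
        constants = None
        if self.thermal_k1 is not None:
            constants = ThermalConstants(k1=self.thermal_k1, k2=self.thermal_k2)
        manual = None
        if self.manual_anchors is not None:
            manual = (tuple(self.manual_anchors[0]), tuple(self.manual_anchors[1]))
        return ProcessParams(
            elevation=self.elevation, station_zom=self.station_zom,
            anemometer_height=self.anemometer_height,
            etrf_cold=self.etrf_cold, etrf_hot=self.etrf_hot,
            manual_anchors=manual, stability=self.stability,
            max_iterations=self.max_iterations, thermal_constants=constants,
            atmospheric_correction=AtmosphericCorrection(
                tau_nb=self.tau_nb, path_radiance=self.path_radiance,
                sky_radiance=self.sky_radiance,
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"invalid run config:\n  - unknown keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def dump(self, path: str | Path) -> Path:
        """Write the resolved configuration for provenance."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path
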