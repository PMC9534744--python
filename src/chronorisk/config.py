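"""Pipeline configuration and run manifests.

Every numeric constant of the analysis protocol (grid resolution, period
length, buffer radius, rarefaction distance, replicate counts, ...) lives in
:class:`PipelineConfig` so that scaled-down runs only touch configuration,
never code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "RunManifest", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PipelineConfig:
    """Constants of the extinction-analysis protocol.

    Distances are kilometres, the grid cell size is in decimal degrees and
    the study window is in calendar years AD.  Defaults mirror the published
    protocol: 0.5-degree cells, ten 30-year periods over 1700-2000, 50 km
    buffers around extant records, 10 km rarefaction, 100 model replicates
    with a 25% test split.
    """

    grid_cell_degrees: float = 0.5
    period_years: int = 30
    study_start: int = 1700
    study_end: int = 2000
    slice_years: int = 10
    buffer_km: float = 50.0
    rarefy_km: float = 10.0
    rarefy_cell_arcmin: float = 5.0
    background_n: int = 10_000
    replicates: int = 100
    prescreen_runs: int = 25
    test_fraction: float = 0.25
    reg_multiplier: float = 1.0
    correlation_threshold: float = 0.7
    collinear_threshold: float = 0.95
    jenks_k: int = 3
    presence_rows: str = "last"
    screen_start: int = 1970
    screen_end: int = 2000
    # synthetic-world knobs (only the scale of the generated domain)
    sim_n_cells_x: int = 66
    sim_n_cells_y: int = 66
    sim_origin_lon: float = 97.0
    sim_origin_lat: float = 18.0
    sim_detection_prob: float = 0.35
    sim_n_extant: int = 159
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_cell_degrees", "buffer_km", "rarefy_km", "rarefy_cell_arcmin"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError(f"test_fraction must lie in (0,1), got {self.test_fraction}")
        if self.study_end <= self.study_start:
            raise ConfigError("study_end must exceed study_start")
        if (self.study_end - self.study_start) % self.period_years != 0:
            raise ConfigError(
                f"period_years={self.period_years} does not divide the "
                f"{self.study_end - self.study_start}-year study window"
            )
        if self.period_years % self.slice_years != 0:
            raise ConfigError("slice_years must divide period_years")
        if self.presence_rows not in ("last", "all"):
            raise ConfigError("presence_rows must be 'last' or 'all'")
        for name in ("background_n", "replicates", "prescreen_runs", "jenks_k"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @property
    def n_periods(self) -> int:
        return (self.study_end - self.study_start) // self.period_years

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to each stage's outputs."""

    stage: str
    seed: int
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[p.name] = _digest(p)

    def write(self, path: str | Path) -> None:
        self.timestamp = self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
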