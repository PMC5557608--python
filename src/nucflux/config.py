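"""Run configuration: defaults, YAML round-trip, strict key checking."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import CellCycleParams

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline defaults in one serializable place.

    Times are minutes, rates 1/min; thresholds follow the analysis
    conventions: retention at r² > 0.8, labeling-bias exclusion at
    F ≤ 0.2, association tests on the top 70% expressed genes at
    α = 0.01, dispersion fitted over 1000 abundance intervals (capped to
    the data density for small synthetic runs).
    """

    seed: int = 0
    # synthetic experiment
    n_genes: int = 300
    n_replicates: int = 2
    time_grid: tuple[float, ...] = (0.0, 30.0, 90.0, 180.0, 300.0, 450.0)
    U: float = 0.073
    pr: float = 0.01
    noise: bool = True
    # cell cycle
    doubling_time_min: float = 1440.0
    F_G1S: float = 0.2
    F_G2M: float = 0.8
    F_M: float = 1.0 / 24.0
    r_nc: float = 0.8
    # preprocessing
    n_bins: int = 1000
    f_min: float = 0.2
    # error models
    noise_span: float = 0.5
    weighting: str = "as_printed"
    # fitting / retention
    r2_threshold: float = 0.8
    # association statistics
    top_fraction: float = 0.7
    alpha: float = 0.01
    # stage toggles
    stages: tuple[str, ...] = ("simulate", "preprocess", "fit", "associate", "report")

    def cell_cycle(self) -> CellCycleParams:
        return CellCycleParams(
            D=self.doubling_time_min,
            F_G1S=self.F_G1S,
            F_G2M=self.F_G2M,
            F_M=self.F_M,
            r_nc=self.r_nc,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("time_grid", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["time_grid"] = list(data["time_grid"])
        data["stages"] = list(data["stages"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def digest(self) -> str:
        """Short hash of the configuration, logged for reproducibility."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
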