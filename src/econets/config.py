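"""Validated pipeline configuration (YAML/JSON single document).

Unknown keys are rejected, so typos fail fast before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSection(_Strict):
    n_channels: int = 58
    fs: float = 500.0
    epoch_len: float = 10.0
    n_epochs: int = 5
    n_per_group: int = 15
    topology_model: str = "ws"
    topology_cost: float = 0.16
    rewire_p: float = 0.2
    preset: str = "planted"  # planted | null
    null_level: float = 1.0
    lattice_strength: float = 1.2
    duration_slope: float = -0.02
    duration_range: tuple[float, float] = (2.0, 25.0)
    noise_sd: float = 1.0


class WaveletSection(_Strict):
    omega0: float = 6.0
    voices_per_octave: int = 4
    mode: str = "real"  # real | magnitude


class MISection(_Strict):
    n_bins: int = 16
    per_epoch: bool = True


class CostGridSection(_Strict):
    start: float = 0.16
    stop: float = 0.50
    step: float = 0.02


class StatisticsSection(_Strict):
    mode: str = "crossed"  # crossed (error df 56 at study scale) | mixed
    analysis_cost: float = 0.28
    correlate_age: bool = False  # age correlations as a negative control


class PipelineConfig(_Strict):
    output_dir: str = "econets_output"
    input_manifest: str | None = None  # if set, skip simulation and read recordings
    downsample_factor: int = 1
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "alpha": (7.97, 15.05),
            "beta": (15.05, 31.25),
            "gamma": (31.25, 50.78),
        }
    )
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    wavelet: WaveletSection = Field(default_factory=WaveletSection)
    mi: MISection = Field(default_factory=MISection)
    cost_grid: CostGridSection = Field(default_factory=CostGridSection)
    null_draws: int = 20
    statistics: StatisticsSection = Field(default_factory=StatisticsSection)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.null_draws < 1:
            raise ValueError("null_draws must be >= 1")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi):
                raise ValueError(f"band {name!r} has invalid edges ({lo}, {hi})")
        if not (0 < self.cost_grid.start <= self.cost_grid.stop <= 1):
            raise ValueError("cost grid must lie within (0, 1]")
        return self

    def config_hash(self) -> str:
        """Stable short hash of the scientific configuration.

        Disk locations (output_dir, input_manifest) are excluded: the same
        analysis written to two places is the same analysis.
        """
        payload = self.model_dump(exclude={"output_dir", "input_manifest"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def apply_profile(self, profile: str) -> "PipelineConfig":
        """``smoke`` shrinks the run for CI; ``full`` is the identity."""
        if profile == "full":
            return self
        if profile != "smoke":
            raise ValueError(f"unknown profile {profile!r}")
        cfg = self.model_copy(deep=True)
        cfg.simulation.n_per_group = 2
        cfg.simulation.n_epochs = 2
        cfg.cost_grid = CostGridSection(start=0.16, stop=0.28, step=0.12)
        return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig(**data)
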