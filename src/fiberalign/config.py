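"""Run configuration: every tunable parameter of the pipeline in one
serializable object, so a saved config fully determines a run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimulateConfig", "OrientConfig", "StatsConfig", "CompareConfig", "RunConfig"]


@dataclass
class SimulateConfig:
    width: int = 256
    height: int = 256
    n_cells: int = 36
    fibers_per_cell: int = 12
    sparse_coverage: float = 0.10
    fiber_length_mean_px: float = 28.0
    fiber_length_sd_px: float = 7.0
    fiber_width_px: float = 1.5
    fiber_intensity: float = 1800.0
    background_level: float = 200.0
    noise_sd: float = 40.0
    cell_type: str = "HUVEC"
    durations_h: list[float] = field(default_factory=lambda: [1.0, 6.0, 24.0])
    n_replicates: int = 3
    shear_dyn_cm2: float = 15.0
    mu: float = 0.0
    base_seed: int = 2024


@dataclass
class OrientConfig:
    sigma_grad: float = 1.5
    sigma_window: float = 6.0
    intensity_quantile: float = 0.75
    coherence_min: float = 0.2
    weighting: str = "coherence"


@dataclass
class StatsConfig:
    bin_width_deg: float = 15.0
    threshold_deg: float = 45.0


@dataclass
class CompareConfig:
    anova_type: int = 1
    family: str = "all"
    star_thresholds: list = field(
        default_factory=lambda: [["***", 0.005], ["**", 0.005], ["*", 0.05]]
    )


@dataclass
class RunConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    orient: OrientConfig = field(default_factory=OrientConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            simulate=SimulateConfig(**raw.get("simulate", {})),
            orient=OrientConfig(**raw.get("orient", {})),
            stats=StatsConfig(**raw.get("stats", {})),
            compare=CompareConfig(**raw.get("compare", {})),
        )
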