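"""Run configuration: one YAML file is the source of truth.

Defaults follow the standard analysis protocol: SUV cutoff 2.5 for
delineation, fixed bin width 0.4 SUV over 0-25 (64 levels), k = 3
clusters, alpha 0.05 with per-table Bonferroni denominators.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class QuantizationConfig:
    bin_width: float = 0.4
    range_min: float = 0.0
    range_max: float = 25.0
    n_levels: int = 64


@dataclass
class SegmentationConfig:
    cutoff: float = 2.5


@dataclass
class ClusteringConfig:
    k: int = 3
    linkage: str = "ward"
    min_cluster_size: int = 2


@dataclass
class StatisticsConfig:
    alpha: float = 0.05
    correlogram_denominator: int = 109
    proportions_denominator: int = 4


@dataclass
class SimulationConfig:
    n_per_archetype: tuple[int, int, int] = (10, 25, 37)
    jitter_sd: float = 0.15
    seed: int = 0


@dataclass
class RunConfig:
    quantization: QuantizationConfig = field(default_factory=QuantizationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    statistics: StatisticsConfig = field(default_factory=StatisticsConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> "RunConfig":
        q = self.quantization
        if q.bin_width <= 0 or q.range_max <= q.range_min or q.n_levels < 2:
            raise ValueError("invalid quantization settings")
        if self.segmentation.cutoff <= 0:
            raise ValueError("segmentation cutoff must be positive")
        c = self.clustering
        if c.k < 2:
            raise ValueError(f"clustering k must be >= 2, got {c.k}")
        if c.linkage not in ("complete", "average", "ward"):
            raise ValueError(f"unsupported linkage {c.linkage!r}")
        if c.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not 0 < self.statistics.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if any(n < 1 for n in self.simulation.n_per_archetype):
            raise ValueError("n_per_archetype entries must be >= 1")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["n_per_archetype"] = list(self.simulation.n_per_archetype)
        return d

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim = dict(raw.get("simulation", {}))
        if "n_per_archetype" in sim:
            sim["n_per_archetype"] = tuple(sim["n_per_archetype"])
        cfg = cls(
            quantization=QuantizationConfig(**raw.get("quantization", {})),
            segmentation=SegmentationConfig(**raw.get("segmentation", {})),
            clustering=ClusteringConfig(**raw.get("clustering", {})),
            statistics=StatisticsConfig(**raw.get("statistics", {})),
            simulation=SimulationConfig(**sim),
        )
        return cfg.validate()
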