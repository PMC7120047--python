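"""Pipeline configuration: validated settings with YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .node_metrics import FilterThresholds
from .simulate import ScenarioConfig

__all__ = ["PipelineConfig"]

ESTIMATORS = ("ml", "counting", "truth")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run depends on, with documented defaults.

    ``estimator``: ``"ml"`` (null fit then free-ratios, the default),
    ``"counting"`` (null fit then ancestral-reconstruction counting), or
    ``"truth"`` (use the simulator's true branch ω — statistics-only runs).
    ``input_dir``, when set, must contain ``trees/*.nhx`` and
    ``alignments/*.fasta`` to analyse instead of simulating.
    """

    n_trees: int = 50
    seed: int = 1
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    estimator: str = "ml"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    b: int = 1000
    statistic: str = "mean_diff"
    ovl_transform: str | None = "log"
    epsilon: float = 1e-6
    species_tree: str | None = None
    input_dir: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.ovl_transform not in (None, "log"):
            raise ValueError("ovl_transform must be null or 'log'")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("scenario"), dict):
            d["scenario"] = ScenarioConfig(**d["scenario"])
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = FilterThresholds(**d["thresholds"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config YAML must define a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
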