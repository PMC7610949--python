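"""Structured simulation configuration.

One document covers every tunable default: task construction (preferences,
count scales), engine precision and learning rates, environment
responsiveness, intervention schedule and pharmacological parameters, and
the diagnostic conventions.  Configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .task import TaskSpec

__all__ = ["SimulationConfig", "load_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Every default named by the model, in one place.

    The values below define the study conditions; docs/methods.md explains
    how each was chosen and its units.
    """

    horizon_days: int = 64
    # preferences: log-preference (utility) per outcome
    preference_start: float = 0.0
    preference_low: float = -1.9
    preference_moderate: float = 0.35
    preference_high: float = 2.0
    preference_cue: float = 0.0
    # agent likelihood counts
    known_count: float = 128.0
    arm_count: float = 0.4
    transition_count_scale: float = 1.0
    # engine
    gamma: float = 16.0
    eta: float = 0.28
    learn_b: bool = True
    # environment
    env_count_scale: float = 10.0
    support_increment: float = 10.0
    start_context: str = "go"
    support_rudolph_outcome: str = "high"
    # pharmacotherapy
    serotonin_bias_go: float = 0.99
    omega: float = 0.9
    # intervention schedule (1-based days)
    adversity_day: int = 28
    support_day: int = 30
    pharma_day: int = 35
    # diagnostics
    mood_metric: str = "expected_post"
    threshold_percentile: float = 5.0

    def __post_init__(self) -> None:
        if self.mood_metric not in ("expected", "expected_post", "realized"):
            raise ConfigError(
                "mood_metric must be 'expected', 'expected_post' or 'realized'")
        if self.support_rudolph_outcome not in ("high", "moderate"):
            raise ConfigError("support_rudolph_outcome must be 'high' or 'moderate'")
        if self.start_context not in ("go", "no-go"):
            raise ConfigError("start_context must be 'go' or 'no-go'")
        if not 0 < self.omega <= 1:
            raise ConfigError("omega must lie in (0, 1]")

    @property
    def preferences(self) -> list[float]:
        return [self.preference_start, self.preference_low,
                self.preference_moderate, self.preference_high,
                self.preference_cue, self.preference_cue]

    def task_spec(self) -> TaskSpec:
        import numpy as np
        return TaskSpec(
            horizon_days=self.horizon_days,
            preference_values=np.array(self.preferences),
            known_count=self.known_count,
            arm_count=self.arm_count,
            transition_count_scale=self.transition_count_scale,
            gamma=self.gamma,
            eta=self.eta,
            learn_b=self.learn_b,
        )

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_config(path: str | Path | None = None) -> SimulationConfig:
    """Load a YAML configuration, or the calibrated defaults if none given."""
    return SimulationConfig.from_yaml(path) if path else SimulationConfig()
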