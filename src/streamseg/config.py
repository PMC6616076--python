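"""Configuration containers tying the pipeline stages together.

`ModelConfig` bundles everything that defines the model apart from the
condition variables (delta_pitch, duration, delta_t): the sequence template,
the input-stage weighting parameters, the competition-stage parameters and
the readout/binning settings.  `RunConfig` adds run-level bookkeeping
(master seed, output directory, fitting and synthetic-study sections) and
can be loaded from YAML or JSON.  Validation happens eagerly, in the
dataclass constructors, before any simulation starts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .competition import CompetitionParams
from .cortical_input import InputStageParams
from .stimulus import DEFAULT_DELTA_T, DEFAULT_RATE, DelayPolicy, SequenceSpec

__all__ = ["ModelConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Full model specification minus the condition variables."""

    presentation_rate: float = DEFAULT_RATE
    tone_duration: float | None = None
    delayed_event_policy: DelayPolicy = "last_b"
    input_stage: InputStageParams = field(default_factory=InputStageParams)
    competition: CompetitionParams = field(default_factory=CompetitionParams)
    bin_width: float = 0.1
    chance_rate: float = 0.5
    rate_clip: float | None = None  # None -> 1 / (2 * n_trials)

    def __post_init__(self) -> None:
        if self.presentation_rate <= 0:
            raise ValueError("presentation_rate must be > 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not 0 < self.chance_rate < 1:
            raise ValueError("chance_rate must lie in (0, 1)")
        if self.rate_clip is not None and not 0 < self.rate_clip < 0.5:
            raise ValueError("rate_clip must lie in (0, 0.5)")

    @property
    def dt(self) -> float:
        return self.competition.dt

    def sequence_spec(
        self, delta_pitch: float, duration: float, delta_t: float = DEFAULT_DELTA_T
    ) -> SequenceSpec:
        return SequenceSpec(
            presentation_rate=self.presentation_rate,
            duration=duration,
            delta_pitch=delta_pitch,
            delta_t=delta_t,
            tone_duration=self.tone_duration,
            delayed_event_policy=self.delayed_event_policy,
        )

    def with_input(self, **changes) -> "ModelConfig":
        return replace(self, input_stage=self.input_stage.with_(**changes))

    def with_(self, **changes) -> "ModelConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        d = dict(d)
        if "input_stage" in d and isinstance(d["input_stage"], dict):
            d["input_stage"] = InputStageParams(**d["input_stage"])
        if "competition" in d and isinstance(d["competition"], dict):
            d["competition"] = CompetitionParams(**d["competition"])
        _reject_unknown(cls, d)
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration for the command-line pipeline."""

    model: ModelConfig = field(default_factory=ModelConfig)
    master_seed: int = 0
    output_dir: str = "streamseg_out"
    n_trials: int = 1000
    delta_pitch: tuple[float, ...] = (0.0, 12.5, 25.0, 50.0, 75.0, 100.0)
    durations: tuple[float, ...] = (1.24, 3.96)
    delta_t: float = DEFAULT_DELTA_T
    fitting: dict[str, Any] = field(default_factory=dict)
    synthetic: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.master_seed < 0:
            raise ValueError("master_seed must be >= 0")
        if not self.delta_pitch or not self.durations:
            raise ValueError("delta_pitch and durations must be non-empty")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig.from_dict(d["model"])
        for key in ("delta_pitch", "durations"):
            if key in d:
                d[key] = tuple(d[key])
        _reject_unknown(cls, d)
        return cls(**d)


def _reject_unknown(cls, d: dict[str, Any]) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)
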