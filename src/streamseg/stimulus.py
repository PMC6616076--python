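"""Event timelines for alternating A/B sound sequences.

The behavioral paradigm presents a sequence of alternating A and B sounds at
a fixed presentation rate (5.89 sounds per second in the study emulated
here).  The listener's task is to detect a small temporal delay (``delta_t``)
imposed on one or more B sounds, which is easiest when the A and B sounds are
heard as separate streams.  This module builds the symbolic event timeline —
onset, duration and label per sound — that drives the cortical input stage;
no audio or electrodogram synthesis is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import pandas as pd

__all__ = [
    "SequenceSpec",
    "Event",
    "EventTimeline",
    "build_sequence",
    "canonical_durations",
]

#: Sequence durations (seconds) used throughout: the short and long
#: conditions of the delay-detection experiments.
SHORT_DURATION = 1.24
LONG_DURATION = 3.96

#: Presentation rate in sounds per second (A and B pooled).
DEFAULT_RATE = 5.89

#: Median temporal delay imposed on the target B sound(s), seconds.
DEFAULT_DELTA_T = 0.0485

DelayPolicy = Literal["none", "last_b", "all_b"]


@dataclass(frozen=True)
class SequenceSpec:
    """Parameters of one alternating A/B sequence condition.

    Parameters
    ----------
    presentation_rate
        Sounds per second, A and B pooled; the inter-onset interval (IOI)
        between consecutive sounds is ``1 / presentation_rate``.
    duration
        Nominal sequence duration in seconds.  The number of sounds is
        ``floor(duration * presentation_rate)``; a partial trailing slot is
        dropped.
    delta_pitch
        Perceptual pitch difference between A and B on a percent scale
        (100 is the reference difference of the emulated study).  Carried on
        the spec because it defines the condition; it does not affect event
        timing.
    delta_t
        Temporal delay (seconds) added to the onset of the B sounds selected
        by ``delayed_event_policy``.
    tone_duration
        Duration of each sound, seconds.  ``None`` selects half the IOI.
    delayed_event_policy
        Which B sounds receive the ``delta_t`` delay: ``"none"``,
        ``"last_b"`` (default; the delay-detection task targets late events)
        or ``"all_b"``.
    """

    presentation_rate: float = DEFAULT_RATE
    duration: float = LONG_DURATION
    delta_pitch: float = 0.0
    delta_t: float = DEFAULT_DELTA_T
    tone_duration: float | None = None
    delayed_event_policy: DelayPolicy = "last_b"

    def __post_init__(self) -> None:
        if self.presentation_rate <= 0:
            raise ValueError("presentation_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.delta_pitch < 0:
            raise ValueError("delta_pitch must be >= 0")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")
        if self.tone_duration is not None and not (0 < self.tone_duration < self.ioi):
            raise ValueError("tone_duration must lie in (0, 1/presentation_rate)")
        if self.delayed_event_policy not in ("none", "last_b", "all_b"):
            raise ValueError(f"unknown delayed_event_policy {self.delayed_event_policy!r}")

    @property
    def ioi(self) -> float:
        """Inter-onset interval between consecutive (undelayed) sounds, s."""
        return 1.0 / self.presentation_rate

    @property
    def effective_tone_duration(self) -> float:
        return self.tone_duration if self.tone_duration is not None else 0.5 * self.ioi

    @property
    def n_events(self) -> int:
        return math.floor(self.duration * self.presentation_rate)

    def with_(self, **changes) -> "SequenceSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    label: str  # "A" or "B"

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class EventTimeline:
    """Ordered A/B sound events plus the total sequence span."""

    events: tuple[Event, ...]
    total_duration: float
    spec: SequenceSpec | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for a, b in zip(self.events, self.events[1:]):
            if a.label == b.label:
                raise ValueError("event labels must alternate A,B,A,B,...")
        for e in self.events:
            if e.label not in ("A", "B"):
                raise ValueError(f"unknown event label {e.label!r}")
            if e.offset > self.total_duration + 1e-12:
                raise ValueError("event extends past total_duration")

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self, label: str | None = None) -> list[float]:
        return [e.onset for e in self.events if label is None or e.label == label]

    def last_event(self, label: str) -> Event:
        for e in reversed(self.events):
            if e.label == label:
                return e
        raise ValueError(f"timeline contains no {label!r} events")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "label": [e.label for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, total_duration: float | None = None) -> "EventTimeline":
        events = tuple(
            Event(float(r.onset_s), float(r.duration_s), str(r.label))
            for r in frame.itertuples(index=False)
        )
        if total_duration is None:
            total_duration = max(e.offset for e in events)
        return cls(events=events, total_duration=float(total_duration))

    @classmethod
    def from_csv(cls, path: str | Path, total_duration: float | None = None) -> "EventTimeline":
        return cls.from_frame(pd.read_csv(path), total_duration)


def canonical_durations() -> tuple[float, float]:
    """The (short, long) sequence durations in seconds: ``(1.24, 3.96)``."""
    return (SHORT_DURATION, LONG_DURATION)


def _delayed_indices(labels: list[str], policy: DelayPolicy) -> set[int]:
    b_idx = [i for i, lab in enumerate(labels) if lab == "B"]
    if policy == "none" or not b_idx:
        return set()
    if policy == "last_b":
        return {b_idx[-1]}
    return set(b_idx)


def build_sequence(spec: SequenceSpec) -> EventTimeline:
    """Construct the event timeline for one sequence condition.

    Events start at ``t = 0`` with label A and alternate at the IOI.  B
    events selected by ``spec.delayed_event_policy`` have their onset shifted
    by ``+spec.delta_t``; the shift must not make a B sound collide with or
    pass the following A sound.
    """
    n = spec.n_events
    if n < 1:
        raise ValueError("duration too short: no events fit at this presentation rate")
    ioi = spec.ioi
    tone = spec.effective_tone_duration
    labels = ["A" if i % 2 == 0 else "B" for i in range(n)]
    onsets = [i * ioi for i in range(n)]
    for i in _delayed_indices(labels, spec.delayed_event_policy):
        delayed = onsets[i] + spec.delta_t
        if i + 1 < n and delayed + tone > onsets[i + 1]:
            raise ValueError(
                f"delta_t={spec.delta_t} makes B event {i} collide with the next A onset"
            )
        if delayed + tone > spec.duration:
            raise ValueError(f"delta_t={spec.delta_t} pushes B event {i} past the sequence end")
        onsets[i] = delayed
    events = tuple(Event(onset, tone, lab) for onset, lab in zip(onsets, labels))
    return EventTimeline(events=events, total_duration=spec.duration, spec=spec)
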