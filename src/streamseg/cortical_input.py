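"""Cortical input stage: feature-dependent weighting and pulsatile currents.

The competition network is driven by three input currents, one per percept
unit: ``I_A`` and ``I_B`` for the two segregated-stream units and ``I_AB``
for the integrated unit.  Each sound event excites all three units, with an
amplitude set by a weighting function of the perceptual distance between the
event and the unit's preferred feature value,

    w(dp, t) = Q(t) * L * exp(-R(t) * dp / sigma)

where ``dp`` is the pitch distance in percent, ``L`` an amplitude factor,
``sigma`` the lateral decay constant, and ``Q(t)``, ``R(t)`` exponential
decay profiles (time constant 0.5 s) that implement the amplitude and the
feature-contrast adaptation of the input.  ``Q`` decays below 1 so inputs
weaken slightly over the sequence; ``R`` grows above 1 so the effective
tuning sharpens, progressively starving the integrated unit of cross-feature
input.  The latter is the mechanism that makes segregation build up over
seconds.

During an A event the A unit sits at distance 0, the integrated AB unit at
``delta_pitch / 2`` (midway between the A and B feature values) and the B
unit at ``delta_pitch``; B events are symmetric.  The adaptation clock for
``Q`` and ``R`` runs from sequence onset, not per event.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import EventTimeline

__all__ = [
    "InputStageParams",
    "InputCurrents",
    "adaptation_profile",
    "weight",
    "build_input_currents",
]

UNITS = ("A", "B", "AB")


@dataclass(frozen=True)
class InputStageParams:
    """Parameters of the input weighting function.

    ``L`` and ``sigma`` are the two fit parameters of the framework
    (canonical values L = 0.6 with sigma = 40, or L = 0.35 with sigma = 30
    for the more ambiguous percept regime).  ``tau_ad`` is the shared time
    constant of the ``Q`` and ``R`` profiles (0.5 s).  The endpoint values
    ``q_init/q_asym`` and ``r_init/r_asym`` are declared defaults of this
    package: tuning starts broad (``r_init`` well below 1, so even distant
    features drive the integrated pathway strongly at sequence onset) and
    sharpens toward ``r_asym`` over the first couple of seconds, which
    progressively starves the integrated pathway and produces the rising
    build-up function.
    ``ramp`` is a raised-cosine on/off ramp applied to each event envelope;
    it keeps the input continuous in time, which the fixed-step integrator
    of the competition stage needs for clean convergence.
    """

    L: float = 0.6
    sigma: float = 40.0
    tau_ad: float = 0.5
    q_init: float = 1.0
    q_asym: float = 0.85
    r_init: float = 0.2
    r_asym: float = 1.8
    ramp: float = 0.005

    def __post_init__(self) -> None:
        for name in ("L", "sigma", "tau_ad", "q_init", "q_asym", "r_init", "r_asym"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ramp < 0:
            raise ValueError("ramp must be >= 0")

    def with_(self, **changes) -> "InputStageParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class InputCurrents:
    """Discretized input currents on a common time grid."""

    dt: float
    t: np.ndarray
    I_A: np.ndarray
    I_B: np.ndarray
    I_AB: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("I_A", "I_B", "I_AB"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != time grid length {n}")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_steps(self) -> int:
        return len(self.t)

    def stacked(self) -> np.ndarray:
        """Currents as an (n_steps, 3) array ordered (A, B, AB)."""
        return np.column_stack([self.I_A, self.I_B, self.I_AB])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "I_A": self.I_A, "I_B": self.I_B, "I_AB": self.I_AB})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def adaptation_profile(
    t: float | np.ndarray, init: float, asym: float, tau: float
) -> float | np.ndarray:
    """Exponential relaxation ``asym + (init - asym) * exp(-t / tau)``.

    Monotone between ``init`` at ``t = 0`` and ``asym`` as ``t`` grows;
    negative times are rejected.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = asym + (init - asym) * np.exp(-t / tau)
    return float(out) if out.ndim == 0 else out


def _q(t, p: InputStageParams):
    return adaptation_profile(t, p.q_init, p.q_asym, p.tau_ad)


def _r(t, p: InputStageParams):
    return adaptation_profile(t, p.r_init, p.r_asym, p.tau_ad)


def weight(
    delta_pitch: float | np.ndarray, t: float | np.ndarray, params: InputStageParams
) -> float | np.ndarray:
    """Input weight ``Q(t) * L * exp(-R(t) * delta_pitch / sigma)``.

    Strictly decreasing in ``delta_pitch`` at fixed ``t``; equals
    ``Q(t) * L`` at zero pitch distance; linear in ``L``.
    """
    dp = np.asarray(delta_pitch, dtype=float)
    if np.any(dp < 0):
        raise ValueError("delta_pitch must be >= 0")
    out = _q(t, params) * params.L * np.exp(-_r(t, params) * dp / params.sigma)
    return float(out) if np.ndim(out) == 0 else out


def event_envelopes(
    timeline: EventTimeline, t: np.ndarray, ramp: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-label summed event envelopes sampled on the grid ``t``.

    Returns ``(env_A, env_B)``, each in [0, 1].  With ``ramp > 0`` each
    event carries raised-cosine on/off flanks of that length (shortened if
    the event is too brief for two full flanks); with ``ramp = 0`` the
    envelope is rectangular on ``[onset, offset)``.
    """
    env = {"A": np.zeros_like(t), "B": np.zeros_like(t)}
    for ev in timeline.events:
        r = min(ramp, ev.duration / 2)
        x = t - ev.onset
        if r == 0:
            e = ((x >= 0) & (x < ev.duration)).astype(float)
        else:
            e = np.zeros_like(t)
            rise = (x >= 0) & (x < r)
            e[rise] = 0.5 * (1 - np.cos(np.pi * x[rise] / r))
            flat = (x >= r) & (x < ev.duration - r)
            e[flat] = 1.0
            fall = (x >= ev.duration - r) & (x < ev.duration)
            e[fall] = 0.5 * (1 - np.cos(np.pi * (ev.duration - x[fall]) / r))
        env[ev.label] += e
    return env["A"], env["B"]


def build_input_currents(
    timeline: EventTimeline,
    delta_pitch: float,
    params: InputStageParams,
    dt: float,
) -> InputCurrents:
    """Convert an event timeline into the three unit input currents.

    During an A event the units receive ``w(0, t)`` (A), ``w(delta_pitch,
    t)`` (B) and ``w(delta_pitch / 2, t)`` (AB); B events are symmetric.
    The AB unit is therefore driven on every sound at intermediate strength,
    while each stream unit alternates between strong (own) and weak (other)
    drive.  ``dt`` must resolve the tone envelope (``dt <= tone / 4``).
    """
    if delta_pitch < 0:
        raise ValueError("delta_pitch must be >= 0")
    tone = min(e.duration for e in timeline.events)
    if dt > tone / 4:
        raise ValueError(f"dt={dt} too coarse for tone duration {tone} (need dt <= tone/4)")
    n = int(round(timeline.total_duration / dt))
    t = np.arange(n) * dt
    env_a, env_b = event_envelopes(timeline, t, params.ramp)
    q = _q(t, params)
    r = _r(t, params)
    w_same = q * params.L  # distance 0
    w_cross = w_same * np.exp(-r * delta_pitch / params.sigma)
    w_mid = w_same * np.exp(-r * (delta_pitch / 2) / params.sigma)
    return InputCurrents(
        dt=dt,
        t=t,
        I_A=env_a * w_same + env_b * w_cross,
        I_B=env_b * w_same + env_a * w_cross,
        I_AB=(env_a + env_b) * w_mid,
    )
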