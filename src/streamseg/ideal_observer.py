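"""Ideal-observer linkage from percept proportions to d' scores.

The behavioral task asks listeners to detect a temporal delay on a late B
sound, which is easy when the streams are heard separately and at chance
when they are integrated.  The ideal observer (IO) therefore assumes a 100%
hit rate on segregated trials and chance-level performance on integrated
trials.  With a fraction ``p`` of segregated trials the hit rate is

    H = p + (1 - p) * chance,    F = chance,

both clipped away from 0 and 1 by ``1 / (2N)`` (the standard correction for
perfect rates at N trials), and ``d' = Phi^{-1}(H) - Phi^{-1}(F)``.

`predict_condition` runs the full pipeline — stimulus timeline, input
currents, N competition trials, per-trial classification in the decision
window around the delayed event — and converts the segregated-trial
fraction into a d' prediction for one (delta_pitch, duration, delta_t)
condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from . import buildup as _buildup
from .competition import simulate_trials
from .config import ModelConfig
from .cortical_input import build_input_currents
from .stimulus import build_sequence

__all__ = ["IOConfig", "DprimePrediction", "dprime_from_proportion", "predict_condition"]


@dataclass(frozen=True)
class IOConfig:
    """Ideal-observer conventions.

    ``chance_rate`` is the performance on integrated trials (0.5 for the
    yes/no delay-detection geometry; other values support 2AFC-style
    variants).  ``rate_clip`` bounds hit/false-alarm rates away from 0 and
    1; ``None`` selects the ``1 / (2N)`` convention.
    """

    chance_rate: float = 0.5
    rate_clip: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.chance_rate < 1:
            raise ValueError("chance_rate must lie in (0, 1)")
        if self.rate_clip is not None and not 0 < self.rate_clip < 0.5:
            raise ValueError("rate_clip must lie in (0, 0.5)")

    def clip_value(self, n_trials: int) -> float:
        return self.rate_clip if self.rate_clip is not None else 1.0 / (2 * n_trials)


@dataclass(frozen=True)
class DprimePrediction:
    """Model-predicted sensitivity for one stimulus condition."""

    delta_pitch: float
    duration: float
    delta_t: float
    p_segregated: float
    dprime: float
    n_trials: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_segregated <= 1:
            raise ValueError("p_segregated must lie in [0, 1]")


def dprime_from_proportion(p: float, n_trials: int, cfg: IOConfig | None = None) -> float:
    """IO d' for a segregated-trial proportion ``p`` out of ``n_trials``.

    Monotone non-decreasing in ``p``; 0 at ``p = 0``; bounded above by
    ``Phi^{-1}(1 - clip) - Phi^{-1}(chance)``.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = cfg or IOConfig()
    clip = cfg.clip_value(n_trials)
    hit = p + (1.0 - p) * cfg.chance_rate
    fa = cfg.chance_rate
    hit = min(max(hit, clip), 1.0 - clip)
    fa = min(max(fa, clip), 1.0 - clip)
    return float(ndtri(hit) - ndtri(fa))


def predict_condition(
    delta_pitch: float,
    duration: float,
    delta_t: float,
    model_config: ModelConfig | None = None,
    n_trials: int = 1000,
    master_seed: int = 0,
    condition_index: int = 0,
    return_traces: bool = False,
):
    """Predict d' for one (delta_pitch, duration, delta_t) condition.

    Runs ``n_trials`` independent competition trials, classifies each trial
    in the decision window around the delayed B event, and converts the
    segregated fraction into d'.  Reruns with identical arguments are
    bit-identical.  With ``return_traces=True`` also returns the percept
    traces (for build-up analysis of the same simulations).
    """
    cfg = model_config or ModelConfig()
    spec = cfg.sequence_spec(delta_pitch, duration, delta_t)
    timeline = build_sequence(spec)
    currents = build_input_currents(timeline, delta_pitch, cfg.input_stage, cfg.dt)
    traces = simulate_trials(
        currents, cfg.competition, n_trials, master_seed, condition_index=condition_index
    )
    w0, w1 = _buildup.decision_window(timeline)
    labels = [_buildup.classify_trial(tr, w0, w1) for tr in traces]
    p = float(np.mean(labels))
    io_cfg = IOConfig(chance_rate=cfg.chance_rate, rate_clip=cfg.rate_clip)
    pred = DprimePrediction(
        delta_pitch=delta_pitch,
        duration=duration,
        delta_t=delta_t,
        p_segregated=p,
        dprime=dprime_from_proportion(p, n_trials, io_cfg),
        n_trials=n_trials,
    )
    return (pred, traces) if return_traces else pred


def predictions_to_frame(preds: Sequence[DprimePrediction], master_seed: int | None = None) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "delta_pitch": [p.delta_pitch for p in preds],
            "duration_s": [p.duration for p in preds],
            "delta_t_s": [p.delta_t for p in preds],
            "p_segregated": [p.p_segregated for p in preds],
            "dprime": [p.dprime for p in preds],
            "n_trials": [p.n_trials for p in preds],
        }
    )
    if master_seed is not None:
        frame["seed"] = master_seed
    return frame


def save_predictions(
    preds: Sequence[DprimePrediction], path: str | Path, master_seed: int | None = None
) -> None:
    predictions_to_frame(preds, master_seed).to_csv(path, index=False)
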