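"""Fitting the input-weighting parameters to behavioral d' tables.

Only the input-stage weighting parameters — the lateral decay constant
``sigma`` and optionally the amplitude factor ``L`` — are searched; the
competition-stage equations and parameters are untouched by construction.
The objective is the averaged mean error (AME): the mean absolute
difference between the model-predicted d' and the behavioral mean d'
across all (delta_pitch, duration) conditions.  RMSE is available as an
alternative objective.

The search is a real-coded genetic algorithm (tournament selection, blend
crossover, Gaussian mutation, elitism of one), which tolerates the
Monte-Carlo noise left in the objective by the finite number of simulated
trials per evaluation.  Two variance-reduction devices keep that noise
small and common across candidates: every candidate is evaluated with the
same per-trial noise realizations (common random numbers), and those
realizations are generated once per fit.  Because the competition-stage
noise does not depend on (sigma, L), each candidate evaluation reduces to
rebuilding the three input currents and re-integrating the network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import buildup as _buildup
from ._rng import generator
from .competition import _integrate_batch, ou_noise
from .config import ModelConfig
from .cortical_input import adaptation_profile, event_envelopes
from .ideal_observer import IOConfig, dprime_from_proportion
from .stimulus import DEFAULT_DELTA_T, build_sequence

__all__ = ["BehavioralTable", "FitConfig", "FitResult", "ame", "fit"]

REQUIRED_COLUMNS = ("delta_pitch", "duration_s", "dprime_mean")
DEFAULT_BOUNDS = {"sigma": (5.0, 150.0), "L": (0.05, 1.2)}


@dataclass(frozen=True)
class BehavioralTable:
    """Mean behavioral d' per (delta_pitch, duration) condition.

    Wraps a DataFrame with columns ``delta_pitch, duration_s, dprime_mean``
    and optionally ``dprime_sd, n_listeners``.  Condition pairs must be
    unique and d' means finite.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"behavioral table missing columns: {missing}")
        if self.frame.empty:
            raise ValueError("behavioral table is empty")
        if self.frame.duplicated(subset=["delta_pitch", "duration_s"]).any():
            raise ValueError("duplicate (delta_pitch, duration_s) conditions")
        if not np.all(np.isfinite(self.frame["dprime_mean"])):
            raise ValueError("dprime_mean must be finite")

    def __len__(self) -> int:
        return len(self.frame)

    def conditions(self) -> list[tuple[float, float]]:
        return [
            (float(r.delta_pitch), float(r.duration_s))
            for r in self.frame.itertuples(index=False)
        ]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, column_map: dict[str, str] | None = None
    ) -> "BehavioralTable":
        """Read a table from CSV.

        ``column_map`` renames source columns to the schema above, e.g.
        ``{"dPitch": "delta_pitch", "dur": "duration_s", "dprime":
        "dprime_mean"}`` for externally deposited tables.
        """
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"behavioral data file not found: {path}")
        frame = pd.read_csv(path)
        if column_map:
            frame = frame.rename(columns=column_map)
        return cls(frame=frame)


@dataclass(frozen=True)
class FitConfig:
    free_parameters: tuple[str, ...] = ("sigma",)
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    ga_population: int = 24
    ga_generations: int = 40
    ga_seed: int = 0
    n_trials_per_eval: int = 200
    final_n_trials: int = 1000
    objective: str = "ame"  # or "rmse"
    crossover_alpha: float = 0.3
    mutation_prob: float = 0.35
    mutation_scale: float = 0.12  # fraction of each parameter's range

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise ValueError("need at least one free parameter")
        for p in self.free_parameters:
            if p not in ("sigma", "L"):
                raise ValueError(f"unknown free parameter {p!r} (only sigma and L are searchable)")
            lo, hi = self.bounds[p]
            if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo <= hi):
                raise ValueError(f"bounds for {p} must be finite, positive and ordered")
        if self.ga_population < 4:
            raise ValueError("ga_population must be >= 4")
        if self.ga_generations < 1 or self.n_trials_per_eval < 1:
            raise ValueError("ga_generations and n_trials_per_eval must be >= 1")
        if self.objective not in ("ame", "rmse"):
            raise ValueError("objective must be 'ame' or 'rmse'")


def _round_sig(x: float, n: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


@dataclass(frozen=True)
class FitResult:
    """Best parameter vector found by the GA and its objective value.

    ``sigma_hat``/``L_hat`` and ``ame`` are the raw values; the
    presentation convention of the emulated study (sigma and AME to the
    first significant figure, L to the second) is available via
    :meth:`rounded`.
    """

    sigma_hat: float
    L_hat: float | None
    ame: float
    ame_final: float
    generations_log: tuple[float, ...]
    seed: int
    config: FitConfig

    def rounded(self) -> dict[str, float]:
        out = {"sigma": _round_sig(self.sigma_hat, 1), "ame": _round_sig(self.ame, 1)}
        if self.L_hat is not None:
            out["L"] = _round_sig(self.L_hat, 2)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sigma_hat": self.sigma_hat,
            "L_hat": self.L_hat,
            "ame": self.ame,
            "ame_final": self.ame_final,
            "rounded": self.rounded(),
            "generations_log": list(self.generations_log),
            "seed": self.seed,
            "config": {
                "free_parameters": list(self.config.free_parameters),
                "bounds": {k: list(v) for k, v in self.config.bounds.items()},
                "ga_population": self.config.ga_population,
                "ga_generations": self.config.ga_generations,
                "n_trials_per_eval": self.config.n_trials_per_eval,
                "final_n_trials": self.config.final_n_trials,
                "objective": self.config.objective,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def ame(
    predictions: Sequence[Any] | pd.DataFrame,
    data: BehavioralTable,
    objective: str = "ame",
) -> float:
    """Averaged mean error between predictions and behavioral means.

    ``predictions`` is a sequence of DprimePrediction (or a DataFrame with
    columns delta_pitch, duration_s, dprime); every data condition must
    have a matching prediction.
    """
    if isinstance(predictions, pd.DataFrame):
        pred_map = {
            (float(r.delta_pitch), float(r.duration_s)): float(r.dprime)
            for r in predictions.itertuples(index=False)
        }
    else:
        pred_map = {(p.delta_pitch, p.duration): p.dprime for p in predictions}
    errors = []
    for row in data.frame.itertuples(index=False):
        key = (float(row.delta_pitch), float(row.duration_s))
        if key not in pred_map:
            raise ValueError(f"no prediction for condition {key}")
        errors.append(abs(pred_map[key] - float(row.dprime_mean)))
    errors = np.asarray(errors)
    return float(np.sqrt(np.mean(errors**2)) if objective == "rmse" else errors.mean())


class _ConditionEval:
    """Cached per-condition machinery for repeated (sigma, L) evaluations.

    Holds the timeline-derived envelopes, the Q/R profiles, the decision
    window mask and one fixed set of noise paths, so that evaluating a
    candidate only rebuilds the three currents and re-integrates.
    """

    def __init__(
        self,
        delta_pitch: float,
        duration: float,
        delta_t: float,
        model: ModelConfig,
        n_trials: int,
        master_seed: int,
        condition_index: int,
    ):
        self.delta_pitch = delta_pitch
        self.duration = duration
        self.n_trials = n_trials
        spec = model.sequence_spec(delta_pitch, duration, delta_t)
        timeline = build_sequence(spec)
        dt = model.dt
        n = int(round(timeline.total_duration / dt))
        self.t = np.arange(n) * dt
        p = model.input_stage
        self.env_a, self.env_b = event_envelopes(timeline, self.t, p.ramp)
        self.q = adaptation_profile(self.t, p.q_init, p.q_asym, p.tau_ad)
        self.r = adaptation_profile(self.t, p.r_init, p.r_asym, p.tau_ad)
        w0, w1 = _buildup.decision_window(timeline)
        self.window = (self.t >= w0) & (self.t < w1)
        comp = model.competition
        self.comp = comp
        self.noise = np.ascontiguousarray(
            ou_noise(n_trials, n, dt, comp.tau_n, comp.gamma, master_seed, condition_index)
        )

    def currents(self, sigma: float, L: float) -> np.ndarray:
        w_same = self.q * L
        w_cross = w_same * np.exp(-self.r * self.delta_pitch / sigma)
        w_mid = w_same * np.exp(-self.r * (self.delta_pitch / 2) / sigma)
        out = np.empty((len(self.t), 3))
        out[:, 0] = self.env_a * w_same + self.env_b * w_cross
        out[:, 1] = self.env_b * w_same + self.env_a * w_cross
        out[:, 2] = (self.env_a + self.env_b) * w_mid
        return out

    def p_segregated(self, sigma: float, L: float) -> float:
        c = self.comp
        seg = _integrate_batch(
            self.currents(sigma, L),
            self.noise,
            c.beta_i,
            c.beta_ab_out,
            c.beta_ab_in,
            c.alpha,
            c.g,
            c.tau_u,
            c.tau_a,
            c.gain_slope,
            c.gain_threshold,
            c.dt,
        )
        in_win = seg[:, self.window]
        labels = in_win.sum(axis=1) * 2 >= in_win.shape[1]
        return float(labels.mean())

    def dprime(self, sigma: float, L: float, io_cfg: IOConfig) -> float:
        return dprime_from_proportion(self.p_segregated(sigma, L), self.n_trials, io_cfg)


def _make_evaluator(
    data: BehavioralTable,
    cfg: FitConfig,
    model: ModelConfig,
    n_trials: int,
    delta_t: float,
):
    evals = [
        _ConditionEval(dp, dur, delta_t, model, n_trials, cfg.ga_seed, idx)
        for idx, (dp, dur) in enumerate(data.conditions())
    ]
    targets = data.frame["dprime_mean"].to_numpy(dtype=float)
    io_cfg = IOConfig(chance_rate=model.chance_rate, rate_clip=model.rate_clip)

    def objective(vec: np.ndarray) -> float:
        params = dict(zip(cfg.free_parameters, vec))
        sigma = params.get("sigma", model.input_stage.sigma)
        L = params.get("L", model.input_stage.L)
        preds = np.array([ev.dprime(sigma, L, io_cfg) for ev in evals])
        err = np.abs(preds - targets)
        return float(np.sqrt(np.mean(err**2)) if cfg.objective == "rmse" else err.mean())

    return objective


def _evaluate_once(
    data: BehavioralTable,
    cfg: FitConfig,
    model: ModelConfig,
    n_trials: int,
    delta_t: float,
    vec: np.ndarray,
) -> float:
    """Single objective evaluation with fresh noise, one condition at a
    time (bounded memory even at large ``n_trials``)."""
    params = dict(zip(cfg.free_parameters, vec))
    sigma = params.get("sigma", model.input_stage.sigma)
    L = params.get("L", model.input_stage.L)
    io_cfg = IOConfig(chance_rate=model.chance_rate, rate_clip=model.rate_clip)
    errors = []
    for idx, ((dp, dur), row) in enumerate(
        zip(data.conditions(), data.frame.itertuples(index=False))
    ):
        ev = _ConditionEval(dp, dur, delta_t, model, n_trials, cfg.ga_seed, 10_000 + idx)
        errors.append(abs(ev.dprime(sigma, L, io_cfg) - float(row.dprime_mean)))
    errors = np.asarray(errors)
    return float(np.sqrt(np.mean(errors**2)) if cfg.objective == "rmse" else errors.mean())


def fit(
    data: BehavioralTable,
    cfg: FitConfig | None = None,
    model_config: ModelConfig | None = None,
    delta_t: float = DEFAULT_DELTA_T,
) -> FitResult:
    """Genetic-algorithm fit of the free weighting parameters to ``data``.

    Reproducible for a fixed ``cfg.ga_seed``; the per-generation best
    objective is non-increasing (elitism).  The winning vector is
    re-evaluated at ``cfg.final_n_trials`` with fresh noise and that value
    reported as ``ame_final``.
    """
    cfg = cfg or FitConfig()
    model = model_config or ModelConfig()
    rng = generator(cfg.ga_seed, 2**20)
    names = cfg.free_parameters
    lo = np.array([cfg.bounds[p][0] for p in names])
    hi = np.array([cfg.bounds[p][1] for p in names])
    span = hi - lo

    objective = _make_evaluator(data, cfg, model, cfg.n_trials_per_eval, delta_t)
    cache: dict[tuple, float] = {}

    def evaluate(vec: np.ndarray) -> float:
        key = tuple(np.round(vec, 10))
        if key not in cache:
            try:
                cache[key] = objective(vec)
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(f"objective evaluation failed at {dict(zip(names, vec))}") from exc
        return cache[key]

    pop = lo + rng.random((cfg.ga_population, len(names))) * span
    pop[0] = 0.5 * (lo + hi)  # deterministic mid-point anchor
    fitness = np.array([evaluate(v) for v in pop])
    log: list[float] = []

    for _ in range(cfg.ga_generations):
        order = np.argsort(fitness)
        elite = pop[order[0]].copy()
        log.append(float(fitness[order[0]]))
        children = [elite]
        while len(children) < cfg.ga_population:
            pa = _tournament(pop, fitness, rng)
            pb = _tournament(pop, fitness, rng)
            child = _blend(pa, pb, cfg.crossover_alpha, rng)
            child = _mutate(child, span, cfg, rng)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack(children)
        fitness = np.array([evaluate(v) for v in pop])

    best_idx = int(np.argmin(fitness))
    best, best_f = pop[best_idx], float(fitness[best_idx])
    log.append(best_f)

    ame_final = _evaluate_once(data, cfg, model, cfg.final_n_trials, delta_t, best)

    params = dict(zip(names, best))
    return FitResult(
        sigma_hat=float(params.get("sigma", model.input_stage.sigma)),
        L_hat=float(params["L"]) if "L" in params else None,
        ame=best_f,
        ame_final=float(ame_final),
        generations_log=tuple(log),
        seed=cfg.ga_seed,
        config=cfg,
    )


def _tournament(pop, fitness, rng, k: int = 3):
    idx = rng.integers(0, len(pop), size=min(k, len(pop)))
    return pop[idx[np.argmin(fitness[idx])]]


def _blend(pa, pb, alpha, rng):
    lo = np.minimum(pa, pb)
    hi = np.maximum(pa, pb)
    d = hi - lo
    return rng.uniform(lo - alpha * d, hi + alpha * d + 1e-12)


def _mutate(vec, span, cfg: FitConfig, rng):
    out = vec.copy()
    for i in range(len(out)):
        if rng.random() < cfg.mutation_prob:
            out[i] += rng.normal(0.0, cfg.mutation_scale * span[i])
    return out
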