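"""Three-unit neural competition network and percept readout.

Three firing-rate units encode the candidate percepts of an alternating A/B
sequence: unit A and unit B for the two segregated streams, unit AB for the
integrated (single-stream) percept.  Each unit obeys a Wilson–Cowan-style
rate equation with recurrent excitation, mutual inhibition, slow subtractive
adaptation and additive Ornstein–Uhlenbeck noise inside a saturating gain:

    tau_u * du_j/dt = -u_j + F(I_j + alpha*u_j - sum_k beta_jk*u_k
                               - g*a_j + n_j)
    tau_a * da_j/dt = -a_j + u_j
    F(x) = 1 / (1 + exp(-gain_slope * (x - gain_threshold)))

The inhibition matrix is all-to-all but not uniform: the two stream units
inhibit each other with strength ``beta_i``, the integrated unit inhibits
each stream unit with ``beta_ab_out``, and each stream unit inhibits the
integrated unit with ``beta_ab_in``.  Setting ``beta_ab_in < beta_ab_out``
gives the integrated interpretation a competitive advantage when all inputs
are equal: a zero-feature-difference sequence is then heard as one stream —
the integration default the streaming literature describes — and
segregation takes over only once the feature difference starves the AB unit
of input.  The asymmetry is necessary, not cosmetic: under a uniform
inhibition matrix the three units are statistically exchangeable at zero
feature difference, which forces the segregated readout two thirds of the
time there regardless of every other parameter — not a tenable model of the
task.

The percept readout is winner-take-all on activity: the model encodes
integration at time ``t`` iff ``u_AB(t)`` is strictly larger than both
``u_A(t)`` and ``u_B(t)``, and a segregated percept otherwise (ties count
as segregated).

Integration uses a fixed-step Heun (predictor–corrector) scheme for the
drift at ``dt`` = 1 ms by default, with the OU noise advanced by its exact
one-step update and treated as a known input path within each step.  This
keeps the noise-free dynamics second-order accurate, so halving the step
changes trajectories far less than the 1e-3 tolerance the convergence
suite checks.  All states start at 0 (pre-stimulus silence).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import lfilter

from ._rng import generator
from .cortical_input import InputCurrents

__all__ = [
    "CompetitionParams",
    "Trajectory",
    "PerceptTrace",
    "simulate_trial",
    "simulate_trials",
    "readout",
    "ou_noise",
]


@dataclass(frozen=True)
class CompetitionParams:
    """Competition-stage parameters.

    These are frozen package defaults: they were chosen once so that the
    network exhibits the qualitative streaming phenomenology (integration
    default at zero feature difference, build-up of segregation over
    seconds, monotone feature-difference effect, spontaneous percept
    switching) and are not touched by the fitting stage, which only searches
    the input-weighting parameters.

    ``beta_i`` is the mutual inhibition between the two stream units;
    ``beta_ab_out`` the inhibition the integrated unit exerts on each stream
    unit and ``beta_ab_in`` the inhibition it receives from each
    (``beta_ab_in < beta_ab_out`` is the integration bias).  ``alpha`` is
    recurrent self-excitation, ``g`` the strength of the slow subtractive
    adaptation (time constant ``tau_a``), ``gamma`` the stationary standard
    deviation of the OU noise with correlation time ``tau_n``.  ``tau_u``
    is chosen slower than single events so percept dominance persists
    across the silent gaps of the pulsatile input instead of resetting at
    every tone.
    """

    beta_i: float = 0.85
    beta_ab_out: float = 0.80
    beta_ab_in: float = 0.30
    alpha: float = 0.6
    g: float = 0.15
    tau_u: float = 0.08
    tau_a: float = 1.2
    gamma: float = 0.09
    tau_n: float = 0.1
    gain_slope: float = 10.0
    gain_threshold: float = 0.3
    dt: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.beta_i, self.beta_ab_out, self.beta_ab_in, self.g, self.gamma) < 0:
            raise ValueError("inhibition strengths, g and gamma must be >= 0")
        if not (self.tau_a > self.tau_u > 0):
            raise ValueError("need tau_a > tau_u > 0")
        if self.tau_n <= 0:
            raise ValueError("tau_n must be > 0")
        if not (0 < self.dt < self.tau_u / 5):
            raise ValueError("dt must satisfy 0 < dt < tau_u / 5")

    def with_(self, **changes) -> "CompetitionParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class Trajectory:
    """Full state time course of one simulated trial."""

    t: np.ndarray
    u: np.ndarray  # (n_steps, 3): activities of (A, B, AB)
    a: np.ndarray  # (n_steps, 3): adaptation variables
    n: np.ndarray  # (n_steps, 3): OU noise realization

    @property
    def u_A(self) -> np.ndarray:
        return self.u[:, 0]

    @property
    def u_B(self) -> np.ndarray:
        return self.u[:, 1]

    @property
    def u_AB(self) -> np.ndarray:
        return self.u[:, 2]

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for i, unit in enumerate(("A", "B", "AB")):
            cols[f"u_{unit}"] = self.u[:, i]
            cols[f"a_{unit}"] = self.a[:, i]
            cols[f"n_{unit}"] = self.n[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PerceptTrace:
    """Binary percept time course: 1 = segregated, 0 = integrated."""

    t: np.ndarray
    segregated: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) != len(self.segregated):
            raise ValueError("t and segregated must have equal length")
        vals = np.unique(self.segregated)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("segregated must be binary")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "segregated": self.segregated})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@njit(cache=True)
def _drift(IA, IB, IAB, nA, nB, nAB, uA, uB, uAB, aA, aB, aAB,
           beta_i, b_out, b_in, alpha, g, tau_u, tau_a, slope, theta):
    """Right-hand side of the six state equations at one instant."""
    xA = IA + alpha * uA - beta_i * uB - b_out * uAB - g * aA + nA
    xB = IB + alpha * uB - beta_i * uA - b_out * uAB - g * aB + nB
    xAB = IAB + alpha * uAB - b_in * (uA + uB) - g * aAB + nAB
    fA = (1.0 / (1.0 + np.exp(-slope * (xA - theta))) - uA) / tau_u
    fB = (1.0 / (1.0 + np.exp(-slope * (xB - theta))) - uB) / tau_u
    fAB = (1.0 / (1.0 + np.exp(-slope * (xAB - theta))) - uAB) / tau_u
    dA = (uA - aA) / tau_a
    dB = (uB - aB) / tau_a
    dAB = (uAB - aAB) / tau_a
    return fA, fB, fAB, dA, dB, dAB


@njit(cache=True)
def _integrate_batch(I, noise, beta_i, b_out, b_in, alpha, g, tau_u, tau_a, slope, theta, dt):
    """Heun integration of a batch of trials; returns the binary
    segregated indicator (n_trials, n_steps)."""
    n_trials, n_steps = noise.shape[0], I.shape[0]
    seg = np.empty((n_trials, n_steps), dtype=np.uint8)
    h = dt
    for i in range(n_trials):
        uA = uB = uAB = 0.0
        aA = aB = aAB = 0.0
        seg[i, 0] = 1  # all states zero: tie, counts as segregated
        for k in range(1, n_steps):
            f1 = _drift(I[k - 1, 0], I[k - 1, 1], I[k - 1, 2],
                        noise[i, k - 1, 0], noise[i, k - 1, 1], noise[i, k - 1, 2],
                        uA, uB, uAB, aA, aB, aAB,
                        beta_i, b_out, b_in, alpha, g, tau_u, tau_a, slope, theta)
            f2 = _drift(I[k, 0], I[k, 1], I[k, 2],
                        noise[i, k, 0], noise[i, k, 1], noise[i, k, 2],
                        uA + h * f1[0], uB + h * f1[1], uAB + h * f1[2],
                        aA + h * f1[3], aB + h * f1[4], aAB + h * f1[5],
                        beta_i, b_out, b_in, alpha, g, tau_u, tau_a, slope, theta)
            uA += 0.5 * h * (f1[0] + f2[0])
            uB += 0.5 * h * (f1[1] + f2[1])
            uAB += 0.5 * h * (f1[2] + f2[2])
            aA += 0.5 * h * (f1[3] + f2[3])
            aB += 0.5 * h * (f1[4] + f2[4])
            aAB += 0.5 * h * (f1[5] + f2[5])
            seg[i, k] = 0 if (uAB > uA and uAB > uB) else 1
    return seg


@njit(cache=True)
def _integrate_full(I, noise, beta_i, b_out, b_in, alpha, g, tau_u, tau_a, slope, theta, dt):
    """Single-trial Heun integration storing the full state; identical
    update order to `_integrate_batch`."""
    n_steps = I.shape[0]
    u = np.zeros((n_steps, 3))
    a = np.zeros((n_steps, 3))
    h = dt
    for k in range(1, n_steps):
        uA, uB, uAB = u[k - 1, 0], u[k - 1, 1], u[k - 1, 2]
        aA, aB, aAB = a[k - 1, 0], a[k - 1, 1], a[k - 1, 2]
        f1 = _drift(I[k - 1, 0], I[k - 1, 1], I[k - 1, 2],
                    noise[k - 1, 0], noise[k - 1, 1], noise[k - 1, 2],
                    uA, uB, uAB, aA, aB, aAB,
                    beta_i, b_out, b_in, alpha, g, tau_u, tau_a, slope, theta)
        f2 = _drift(I[k, 0], I[k, 1], I[k, 2],
                    noise[k, 0], noise[k, 1], noise[k, 2],
                    uA + h * f1[0], uB + h * f1[1], uAB + h * f1[2],
                    aA + h * f1[3], aB + h * f1[4], aAB + h * f1[5],
                    beta_i, b_out, b_in, alpha, g, tau_u, tau_a, slope, theta)
        u[k, 0] = uA + 0.5 * h * (f1[0] + f2[0])
        u[k, 1] = uB + 0.5 * h * (f1[1] + f2[1])
        u[k, 2] = uAB + 0.5 * h * (f1[2] + f2[2])
        a[k, 0] = aA + 0.5 * h * (f1[3] + f2[3])
        a[k, 1] = aB + 0.5 * h * (f1[4] + f2[4])
        a[k, 2] = aAB + 0.5 * h * (f1[5] + f2[5])
    return u, a


def ou_noise(
    n_trials: int,
    n_steps: int,
    dt: float,
    tau_n: float,
    gamma: float,
    master_seed: int,
    condition_index: int = 0,
) -> np.ndarray:
    """Exact-discretization OU noise paths, shape (n_trials, n_steps, 3).

    Each (trial, unit) pair has an independent stream keyed by
    ``(master_seed, condition_index, trial, unit)``; paths start at 0 and
    relax to stationary s.d. ``gamma`` with correlation time ``tau_n``.
    """
    if gamma == 0:
        return np.zeros((n_trials, n_steps, 3))
    c1 = np.exp(-dt / tau_n)
    c2 = gamma * np.sqrt(1.0 - c1 * c1)
    eps = np.empty((n_trials, n_steps, 3))
    for i in range(n_trials):
        for j in range(3):
            eps[i, :, j] = generator(master_seed, condition_index, i, j).standard_normal(n_steps)
    eps[:, 0, :] = 0.0  # n(0) = 0
    return lfilter([c2], [1.0, -c1], eps, axis=1)


def _check_dt(currents: InputCurrents, params: CompetitionParams) -> None:
    if abs(currents.dt - params.dt) > 1e-12:
        raise ValueError(f"currents dt={currents.dt} does not match params dt={params.dt}")


def _check_finite(u: np.ndarray) -> None:
    if not np.all(np.isfinite(u)):
        raise FloatingPointError(
            "competition dynamics produced non-finite activities; try a smaller dt"
        )


def simulate_trial(
    currents: InputCurrents,
    params: CompetitionParams,
    seed: int,
    noise: np.ndarray | None = None,
) -> tuple[Trajectory, PerceptTrace]:
    """Simulate one trial, returning the full trajectory and percept trace.

    ``seed`` keys the trial's three per-unit noise streams.  A precomputed
    ``noise`` array of shape (n_steps, 3) overrides seeded generation (used
    for exchange-symmetry checks and deterministic probes).
    """
    _check_dt(currents, params)
    if noise is None:
        noise = ou_noise(
            1, currents.n_steps, params.dt, params.tau_n, params.gamma, params.seed, seed
        )[0]
    elif noise.shape != (currents.n_steps, 3):
        raise ValueError("noise must have shape (n_steps, 3)")
    u, a = _integrate_full(
        currents.stacked(),
        np.ascontiguousarray(noise, dtype=float),
        params.beta_i,
        params.beta_ab_out,
        params.beta_ab_in,
        params.alpha,
        params.g,
        params.tau_u,
        params.tau_a,
        params.gain_slope,
        params.gain_threshold,
        params.dt,
    )
    _check_finite(u)
    traj = Trajectory(t=currents.t.copy(), u=u, a=a, n=np.asarray(noise, dtype=float))
    return traj, readout(traj)


def simulate_trials(
    currents: InputCurrents,
    params: CompetitionParams,
    n_trials: int,
    master_seed: int,
    condition_index: int = 0,
    noise: np.ndarray | None = None,
) -> list[PerceptTrace]:
    """Simulate ``n_trials`` independent trials; returns percept traces.

    Per-trial noise streams are keyed by ``(master_seed, condition_index,
    trial, unit)``, so reruns with the same seed are bit-identical and
    different conditions can deliberately share trial seeds (common random
    numbers) by passing the same ``condition_index``.
    """
    _check_dt(currents, params)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if noise is None:
        noise = ou_noise(
            n_trials,
            currents.n_steps,
            params.dt,
            params.tau_n,
            params.gamma,
            master_seed,
            condition_index,
        )
    seg = _integrate_batch(
        currents.stacked(),
        np.ascontiguousarray(noise, dtype=float),
        params.beta_i,
        params.beta_ab_out,
        params.beta_ab_in,
        params.alpha,
        params.g,
        params.tau_u,
        params.tau_a,
        params.gain_slope,
        params.gain_threshold,
        params.dt,
    )
    t = currents.t
    return [PerceptTrace(t=t, segregated=seg[i]) for i in range(n_trials)]


def readout(traj: Trajectory) -> PerceptTrace:
    """Winner-take-all percept readout.

    Integration (0) iff the AB activity strictly exceeds both stream
    activities; segregated (1) otherwise, including exact ties.
    """
    integrated = (traj.u[:, 2] > traj.u[:, 0]) & (traj.u[:, 2] > traj.u[:, 1])
    return PerceptTrace(t=traj.t, segregated=(~integrated).astype(np.uint8))
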