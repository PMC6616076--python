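"""Competition-network dynamics, readout rule, and numerical behavior."""

import numpy as np
import pytest

from streamseg.competition import (
    CompetitionParams,
    PerceptTrace,
    Trajectory,
    ou_noise,
    readout,
    simulate_trial,
    simulate_trials,
)
from streamseg.cortical_input import InputCurrents, build_input_currents
from streamseg.stimulus import SequenceSpec, build_sequence


def constant_currents(i_a, i_b, i_ab, n_steps=1500, dt=0.001) -> InputCurrents:
    t = np.arange(n_steps) * dt
    return InputCurrents(
        dt=dt,
        t=t,
        I_A=np.full(n_steps, i_a),
        I_B=np.full(n_steps, i_b),
        I_AB=np.full(n_steps, i_ab),
    )


def sequence_currents(model, delta_pitch=50.0, duration=1.24):
    tl = build_sequence(model.sequence_spec(delta_pitch, duration))
    return build_input_currents(tl, delta_pitch, model.input_stage, model.dt)


class TestReadout:
    def test_integrated_when_ab_strictly_largest(self):
        u = np.array([[0.3, 0.2, 0.8]])
        traj = Trajectory(t=np.zeros(1), u=u, a=np.zeros((1, 3)), n=np.zeros((1, 3)))
        assert readout(traj).segregated[0] == 0

    def test_segregated_when_a_stream_leads(self):
        u = np.array([[0.8, 0.1, 0.3]])
        traj = Trajectory(t=np.zeros(1), u=u, a=np.zeros((1, 3)), n=np.zeros((1, 3)))
        assert readout(traj).segregated[0] == 1

    def test_exact_tie_counts_as_segregated(self):
        # the rule demands AB *larger than* both streams; a tie fails it
        u = np.array([[0.5, 0.2, 0.5]])
        traj = Trajectory(t=np.zeros(1), u=u, a=np.zeros((1, 3)), n=np.zeros((1, 3)))
        assert readout(traj).segregated[0] == 1


class TestDynamics:
    def test_noise_free_ab_drive_yields_integrated_fixed_point(self, model):
        params = model.competition.with_(gamma=0.0)
        cur = constant_currents(0.05, 0.05, 0.9)
        traj, trace = simulate_trial(cur, params, seed=0)
        tail = slice(-200, None)
        # settled: activities stop moving
        assert np.abs(np.diff(traj.u[tail], axis=0)).max() < 1e-6
        assert np.all(traj.u[tail, 2] > traj.u[tail, 0])
        assert np.all(traj.u[tail, 2] > traj.u[tail, 1])
        assert np.all(trace.segregated[tail] == 0)

    def test_identical_zero_input_keeps_stream_units_equal(self, model):
        # A and B obey identical equations, so noise-free equal input keeps
        # them exactly equal; the integrated unit follows different
        # (integration-biased) couplings and is allowed to differ.
        params = model.competition.with_(gamma=0.0)
        cur = constant_currents(0.0, 0.0, 0.0, n_steps=500)
        traj, _ = simulate_trial(cur, params, seed=0)
        np.testing.assert_array_equal(traj.u[:, 0], traj.u[:, 1])
        np.testing.assert_array_equal(traj.a[:, 0], traj.a[:, 1])

    def test_uniform_inhibition_keeps_all_units_equal(self, model):
        # with the inhibition matrix made uniform the three units are fully
        # exchangeable and stay identical under equal drive
        params = model.competition.with_(
            gamma=0.0, beta_ab_in=model.competition.beta_i, beta_ab_out=model.competition.beta_i
        )
        cur = constant_currents(0.1, 0.1, 0.1, n_steps=500)
        traj, _ = simulate_trial(cur, params, seed=0)
        np.testing.assert_array_equal(traj.u[:, 0], traj.u[:, 1])
        # AB sums its inhibition in one expression, so agreement is only
        # up to floating-point associativity
        np.testing.assert_allclose(traj.u[:, 0], traj.u[:, 2], atol=1e-12)

    def test_same_seed_bit_identical(self, model):
        cur = sequence_currents(model, 50.0, 1.24)
        t1, p1 = simulate_trial(cur, model.competition, seed=7)
        t2, p2 = simulate_trial(cur, model.competition, seed=7)
        np.testing.assert_array_equal(t1.u, t2.u)
        np.testing.assert_array_equal(p1.segregated, p2.segregated)

    def test_different_seeds_differ(self, model):
        cur = sequence_currents(model, 50.0, 1.24)
        t1, _ = simulate_trial(cur, model.competition, seed=7)
        t2, _ = simulate_trial(cur, model.competition, seed=8)
        assert np.abs(t1.u - t2.u).max() > 1e-3

    def test_a_b_exchange_symmetry_is_exact(self, model):
        params = model.competition
        cur = sequence_currents(model, 50.0, 1.24)
        noise = ou_noise(1, cur.n_steps, params.dt, params.tau_n, params.gamma, 5)[0]
        swapped_currents = InputCurrents(
            dt=cur.dt, t=cur.t, I_A=cur.I_B, I_B=cur.I_A, I_AB=cur.I_AB
        )
        swapped_noise = noise[:, [1, 0, 2]]
        traj, _ = simulate_trial(cur, params, seed=0, noise=noise)
        traj_sw, _ = simulate_trial(swapped_currents, params, seed=0, noise=swapped_noise)
        np.testing.assert_array_equal(traj.u[:, 0], traj_sw.u[:, 1])
        np.testing.assert_array_equal(traj.u[:, 1], traj_sw.u[:, 0])
        np.testing.assert_array_equal(traj.u[:, 2], traj_sw.u[:, 2])

    def test_activities_bounded_in_unit_interval(self, model):
        cur = sequence_currents(model, 100.0, 1.24)
        for seed in range(3):
            traj, _ = simulate_trial(cur, model.competition, seed=seed)
            assert traj.u.min() >= 0.0 and traj.u.max() <= 1.0

    def test_fine_dt_convergence_noise_free(self, model):
        """Halving (and 10x-refining) the step leaves the noise-free
        trajectory within 1e-3 sup-norm on a probe stimulus."""
        tl = build_sequence(model.sequence_spec(50.0, 1.0186))
        sols = {}
        for refine in (1, 10):
            dt = model.dt / refine
            params = model.competition.with_(gamma=0.0, dt=dt)
            cur = build_input_currents(tl, 50.0, model.input_stage, dt)
            traj, _ = simulate_trial(cur, params, seed=0)
            sols[refine] = traj.u[:: refine if refine > 1 else 1]
        n = min(map(len, sols.values()))
        assert np.abs(sols[1][:n] - sols[10][:n]).max() < 1e-3

    def test_batch_matches_single_trial(self, model):
        cur = sequence_currents(model, 50.0, 1.24)
        params = model.competition
        traces = simulate_trials(cur, params, n_trials=3, master_seed=3, condition_index=2)
        for i, batch_trace in enumerate(traces):
            noise = ou_noise(
                i + 1, cur.n_steps, params.dt, params.tau_n, params.gamma, 3, 2
            )[i]
            _, single = simulate_trial(cur, params, seed=0, noise=noise)
            np.testing.assert_array_equal(batch_trace.segregated, single.segregated)

    def test_mismatched_dt_rejected(self, model):
        cur = sequence_currents(model, 50.0, 1.24)
        with pytest.raises(ValueError, match="dt"):
            simulate_trial(cur, model.competition.with_(dt=0.002), seed=0)


class TestOUNoise:
    def test_stationary_sd_matches_gamma(self):
        paths = ou_noise(20, 4000, 0.001, 0.1, 0.09, master_seed=0)
        # discard transient from the n(0)=0 start
        sd = paths[:, 2000:, :].std()
        assert sd == pytest.approx(0.09, rel=0.05)

    def test_autocorrelation_time(self):
        paths = ou_noise(50, 3000, 0.001, 0.1, 0.09, master_seed=1)
        x = paths[:, 1000:, 0]
        lag = 100  # samples = tau_n
        num = np.mean((x[:, :-lag] - x.mean()) * (x[:, lag:] - x.mean()))
        rho = num / x.var()
        assert rho == pytest.approx(np.exp(-1), abs=0.05)

    def test_zero_gamma_is_silent(self):
        assert np.all(ou_noise(2, 100, 0.001, 0.1, 0.0, master_seed=0) == 0)


def test_params_validation():
    with pytest.raises(ValueError):
        CompetitionParams(dt=0.05)  # dt too large vs tau_u
    with pytest.raises(ValueError):
        CompetitionParams(tau_a=0.01, tau_u=0.08)  # adaptation must be slow
    with pytest.raises(ValueError):
        CompetitionParams(gamma=-1)


def test_percept_trace_validation():
    with pytest.raises(ValueError):
        PerceptTrace(t=np.arange(3.0), segregated=np.array([0, 1, 2]))
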