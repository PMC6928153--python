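import numpy as np
import pytest

from kurasync.dynamics import (
    IntegrationBlowupError,
    PhaseState,
    SimulationConfig,
    initial_phases,
    kuramoto_rhs,
    order_parameter,
    rk4_integrate,
    run_ensemble,
    run_realization,
    sampling_times,
)
from kurasync.graphs import draw_frequencies, make_2dll, make_full_graph
from kurasync.meanfield import steady_state_r
from conftest import network_from_dense, ring_network


class TestSamplingTimes:
    def test_first_instant_is_two(self):
        assert sampling_times(10.0)[0] == 2.0

    def test_schedule_formula(self):
        t = sampling_times(100.0, base=1.08)
        ks = np.arange(len(t))
        assert np.allclose(t, 1.0 + 1.08 ** ks)
        assert np.isclose(t[10], 1.0 + 1.08 ** 10)  # ~3.1589

    def test_horizon_cutoff(self):
        t = sampling_times(1000.0)
        assert len(t) == 90  # k = 0..89
        assert t[-1] == 1.0 + 1.08 ** 89
        assert t[-1] <= 1000.0 < 1.0 + 1.08 ** 90

    def test_strictly_increasing(self):
        t = sampling_times(500.0)
        assert np.all(np.diff(t) > 0)

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            sampling_times(1.5)


class TestOrderParameter:
    def test_full_coherence(self):
        assert np.isclose(order_parameter(np.full(17, 1.3)), 1.0)

    def test_uniformly_spaced_phases_cancel(self):
        for n in (2, 5, 8):
            theta = 2 * np.pi * np.arange(n) / n
            assert order_parameter(theta) < 1e-12

    def test_two_oscillators_quarter_turn(self):
        assert np.isclose(order_parameter(np.array([0.0, np.pi / 2])),
                          np.sqrt(2) / 2)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = order_parameter(rng.uniform(-10, 10, size=rng.integers(1, 50)))
            assert 0.0 <= r <= 1.0


class TestKuramotoRhs:
    def test_isolated_node_keeps_intrinsic_frequency(self):
        dense = np.zeros((3, 3))
        dense[0, 1] = dense[1, 0] = 1.0
        net = network_from_dense(dense)
        omega = np.array([0.3, -0.2, 1.7])
        vel = kuramoto_rhs(np.zeros(3), omega, net, K=2.0)
        assert vel[2] == omega[2]

    def test_synchronized_state_moves_at_omega(self):
        net = ring_network(10)
        omega = draw_frequencies(10, seed=2).omega
        vel = kuramoto_rhs(np.full(10, 0.7), omega, net, K=3.0)
        assert np.allclose(vel, omega, atol=1e-14)

    def test_two_node_quarter_turn(self):
        dense = np.array([[0.0, 1.0], [1.0, 0.0]])
        net = network_from_dense(dense)
        vel = kuramoto_rhs(np.array([0.0, np.pi / 2]), np.zeros(2), net, K=1.0)
        assert np.allclose(vel, [1.0, -1.0])

    def test_dimension_mismatch(self):
        net = ring_network(4)
        with pytest.raises(ValueError):
            kuramoto_rhs(np.zeros(3), np.zeros(3), net, K=1.0)


class TestRK4:
    def test_exact_on_uncoupled_flow(self):
        omega = draw_frequencies(20, seed=5).omega
        state = PhaseState(theta=np.linspace(0, 1, 20), time=0.0)
        out = rk4_integrate(state, lambda th: omega, dt=0.1, t_target=7.3)
        assert np.allclose(out.theta, state.theta + omega * 7.3, atol=1e-12)
        assert out.time == 7.3

    def test_time_reversal_of_uncoupled_flow(self):
        omega = draw_frequencies(8, seed=1).omega
        state = PhaseState(theta=np.zeros(8))
        fwd = rk4_integrate(state, lambda th: omega, 0.1, 5.0)
        back = rk4_integrate(PhaseState(fwd.theta, 0.0),
                             lambda th: -omega, 0.1, 5.0)
        assert np.allclose(back.theta, state.theta, atol=1e-12)

    def test_fourth_order_convergence(self):
        net = ring_network(10)
        omega = draw_frequencies(10, seed=3).omega
        theta0 = initial_phases(SimulationConfig(1.0, 10.0, phase_seed=4), 10)

        def rhs(th):
            return kuramoto_rhs(th, omega, net, K=1.0)

        ref = rk4_integrate(PhaseState(theta0.copy()), rhs, 0.0125, 5.0).theta
        err1 = np.max(np.abs(
            rk4_integrate(PhaseState(theta0.copy()), rhs, 0.1, 5.0).theta - ref))
        err2 = np.max(np.abs(
            rk4_integrate(PhaseState(theta0.copy()), rhs, 0.05, 5.0).theta - ref))
        assert err1 < 1e-3
        # halving dt shrinks the error by roughly 2^4
        assert 8.0 < err1 / err2 < 32.0

    def test_blowup_detected(self):
        state = PhaseState(theta=np.ones(3))
        with pytest.raises(IntegrationBlowupError):
            rk4_integrate(state, lambda th: th * np.inf, 0.1, 1.0)


class TestRunRealization:
    def test_coherent_start_begins_synchronized(self, small_2dll):
        cfg = SimulationConfig(coupling_K=0.3, t_max=20.0, init_kind="coherent")
        traj = run_realization(small_2dll, cfg)
        assert traj.R_values[0] > cfg.resolve_threshold(small_2dll.n_nodes)
        assert traj.t_x > traj.times[0] / 2

    def test_zero_coupling_crosses_quickly(self):
        net = ring_network(400)
        crossed_early = 0
        for r in range(30):
            cfg = SimulationConfig(coupling_K=0.0, t_max=50.0,
                                   omega_seed=100 + r, phase_seed=200 + r,
                                   stop_at_crossing=True)
            traj = run_realization(net, cfg)
            if traj.crossed and traj.t_x < 10.0:
                crossed_early += 1
        # uncoupled phases stay at the noise level R ~ 1/sqrt(N)
        assert crossed_early >= 20

    def test_strong_coupling_never_desynchronizes(self):
        # K well above K_c (but with K*dt < 1 so fixed-step RK4 stays stable)
        net = make_full_graph(200, normalized=True)
        cfg = SimulationConfig(coupling_K=8.0, t_max=100.0,
                               omega_seed=7, phase_seed=8)
        traj = run_realization(net, cfg)
        assert not traj.crossed
        assert traj.t_x == cfg.t_max
        assert traj.R_values[-1] > 0.9

    def test_r_bounds_on_every_sample(self, small_2dll):
        cfg = SimulationConfig(coupling_K=0.4, t_max=100.0,
                               omega_seed=1, phase_seed=2)
        traj = run_realization(small_2dll, cfg)
        assert np.all(traj.R_values >= 0.0)
        assert np.all(traj.R_values <= 1.0)

    def test_sample_grid_matches_schedule(self, small_2dll):
        cfg = SimulationConfig(coupling_K=0.4, t_max=60.0)
        traj = run_realization(small_2dll, cfg)
        assert np.array_equal(traj.times, sampling_times(60.0))


class TestEngineConsistency:
    def test_compiled_kernel_matches_numpy_reference(self):
        """The numba engine and the readable NumPy RK4 path must agree."""
        net = make_2dll(5, seed=2)
        omega = draw_frequencies(net.n_nodes, seed=3).omega
        cfg = SimulationConfig(coupling_K=0.6, t_max=10.0,
                               omega_seed=3, phase_seed=4)
        theta0 = initial_phases(cfg, net.n_nodes)

        traj = run_realization(net, cfg)

        state = PhaseState(theta0.copy())
        ref_R = []
        for t_k in traj.times:
            state = rk4_integrate(
                state, lambda th: kuramoto_rhs(th, omega, net, cfg.coupling_K),
                cfg.dt, t_k)
            ref_R.append(order_parameter(state))
        assert np.allclose(traj.R_values, ref_R, rtol=1e-7, atol=1e-9)

    def test_meanfield_shortcut_matches_sparse_kernel(self):
        net = make_full_graph(50, normalized=True)
        cfg = SimulationConfig(coupling_K=2.0, t_max=10.0,
                               omega_seed=5, phase_seed=6)
        mf = run_realization(net, cfg, engine="meanfield")
        sparse = run_realization(net, cfg, engine="sparse")
        assert np.allclose(mf.R_values, sparse.R_values, rtol=1e-7, atol=1e-9)

    def test_rotational_symmetry_of_order_parameter(self):
        net = ring_network(50)
        omega = draw_frequencies(50, seed=9).omega
        rng = np.random.default_rng(10)
        theta0 = rng.uniform(0, 2 * np.pi, 50)

        def rhs(th):
            return kuramoto_rhs(th, omega, net, 1.0)

        a = rk4_integrate(PhaseState(theta0.copy()), rhs, 0.1, 10.0)
        b = rk4_integrate(PhaseState(theta0 + 1.234), rhs, 0.1, 10.0)
        assert np.isclose(order_parameter(a), order_parameter(b), atol=1e-9)

    def test_identical_frequencies_fully_synchronize(self):
        net = make_full_graph(100, normalized=True)
        cfg = SimulationConfig(coupling_K=2.0, t_max=50.0, phase_seed=3)
        theta0 = initial_phases(cfg, 100)
        state = PhaseState(theta0)
        state = rk4_integrate(
            state, lambda th: kuramoto_rhs(th, np.zeros(100), net, 2.0),
            0.1, 50.0)
        assert order_parameter(state) > 0.99


class TestRunEnsemble:
    def test_single_realization_mean_equals_trajectory(self, small_2dll):
        cfg = SimulationConfig(coupling_K=0.4, t_max=30.0)
        ens = run_ensemble(small_2dll, cfg, 1, base_seed=5)
        assert np.array_equal(ens.mean_R, ens.R[0])

    def test_same_seed_bit_identical(self, small_2dll):
        cfg = SimulationConfig(coupling_K=0.45, t_max=60.0,
                               stop_at_crossing=True)
        a = run_ensemble(small_2dll, cfg, 24, base_seed=77)
        b = run_ensemble(small_2dll, cfg, 24, base_seed=77)
        assert np.array_equal(a.t_x, b.t_x)
        assert np.array_equal(a.crossed, b.crossed)

    def test_result_independent_of_batch_size(self, small_2dll):
        cfg = SimulationConfig(coupling_K=0.45, t_max=40.0)
        a = run_ensemble(small_2dll, cfg, 10, base_seed=3, batch_size=10)
        b = run_ensemble(small_2dll, cfg, 10, base_seed=3, batch_size=3)
        assert np.allclose(a.R, b.R, rtol=1e-9, atol=1e-12)

    def test_duration_mode_agrees_with_trajectory_mode(self, small_2dll):
        from dataclasses import replace

        cfg = SimulationConfig(coupling_K=0.45, t_max=60.0)
        full = run_ensemble(small_2dll, cfg, 16, base_seed=11)
        fp = run_ensemble(small_2dll, replace(cfg, stop_at_crossing=True),
                          16, base_seed=11)
        assert np.array_equal(full.crossed, fp.crossed)
        assert np.allclose(full.t_x, fp.t_x)

    def test_n_live_decreases(self, small_2dll):
        cfg = SimulationConfig(coupling_K=0.2, t_max=60.0)
        ens = run_ensemble(small_2dll, cfg, 16, base_seed=2)
        assert np.all(np.diff(ens.n_live) <= 0)
        assert ens.n_live[0] <= 16

    def test_single_precision_matches_double_statistically(self, small_2dll):
        """float32 and float64 kernels agree on ensemble observables
        (individual chaotic trajectories are not comparable)."""
        cfg = SimulationConfig(coupling_K=0.45, t_max=40.0)
        a = run_ensemble(small_2dll, cfg, 32, base_seed=5, precision="double")
        b = run_ensemble(small_2dll, cfg, 32, base_seed=5, precision="single")
        # early times: trajectories still close individually
        assert np.allclose(a.R[:, :10], b.R[:, :10], atol=1e-3)
        # whole horizon: ensemble mean agrees
        assert np.allclose(a.mean_R, b.mean_R, atol=0.05)

    def test_steady_state_matches_meanfield_oracle(self):
        """Simulated stationary R on the normalized complete graph must hit
        the self-consistency fixed point of mean-field theory."""
        net = make_full_graph(1000, normalized=True)
        cfg = SimulationConfig(coupling_K=3.0, t_max=100.0)
        ens = run_ensemble(net, cfg, 20, base_seed=4)
        late = ens.times >= 50.0
        sim = ens.R[:, late].mean()
        assert abs(sim - steady_state_r(3.0)) < 0.05

    def test_output_files(self, small_2dll, tmp_path):
        cfg = SimulationConfig(coupling_K=0.4, t_max=30.0)
        ens = run_ensemble(small_2dll, cfg, 4, base_seed=1)
        ens.write(tmp_path)
        assert (tmp_path / "durations.csv").exists()
        assert (tmp_path / "mean_r.csv").exists()
        assert (tmp_path / "config.json").exists()
        import pandas as pd

        dur = pd.read_csv(tmp_path / "durations.csv")
        assert list(dur.columns) == ["realization", "t_x", "crossed"]
        assert len(dur) == 4
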