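import numpy as np
import pytest

from rctip.systems import (
    BenchmarkSpec,
    MultivariateSeries,
    add_observation_noise,
    densify,
    make_benchmark,
    random_adjacency,
    rewire_random,
    simulate_coupled_lorenz,
    simulate_ks_switch,
    simulate_lorenz63_switch,
    subsample_channels,
)


class TestLorenz63:
    def test_origin_is_an_equilibrium(self):
        s = simulate_lorenz63_switch(10, 6, 200, 500, init=np.zeros(3))
        assert not s.values.any()

    def test_equal_sigmas_mark_no_intensity_change(self):
        s = simulate_lorenz63_switch(9.0, 9.0, 400, 3000, seed=1)
        assert s.truth.delta_h == 0.0
        # matching attractor statistics on both halves (z mean/variance)
        z1, z2 = s.values[:1500, 2], s.values[1500:, 2]
        assert abs(z1.mean() - z2.mean()) < 0.1 * abs(z2.mean())
        assert abs(z1.var() - z2.var()) < 0.25 * z2.var()

    def test_rk4_step_halving_agreement(self):
        # dt=0.02 against a dt=0.002 reference: tight agreement within the
        # chaotic predictability horizon, bounded drift afterwards (the
        # single-step defect of ~7e-5 is amplified exponentially by chaos)
        init = np.array([1.0, 1.0, 1.0])
        coarse = simulate_lorenz63_switch(10, 10, None, 251, dt=0.02, init=init)
        fine = simulate_lorenz63_switch(10, 10, None, 2501, dt=0.002, init=init)
        dev = np.abs(coarse.values - fine.values[::10]).max(axis=1)
        assert dev[:12].max() < 1e-3  # pre-divergence horizon
        assert dev.max() < 0.05      # 5 time units, still shadowing

    def test_sigma_actually_switches_at_t_p(self):
        # truth consistency: re-integrating with the before-parameter matches
        # the run exactly up to t_p and departs afterwards
        s = simulate_lorenz63_switch(7.0, 13.0, 300, 800, seed=4)
        ref = simulate_lorenz63_switch(7.0, 7.0, None, 800, init=s.values[0])
        tp = s.truth.t_p
        assert np.allclose(s.values[:tp + 1], ref.values[:tp + 1], atol=1e-10)
        assert np.abs(s.values[tp + 50] - ref.values[tp + 50]).max() > 1e-3

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate_lorenz63_switch(10, 8, 100, 300, dt=0.0)


class TestCoupledLorenz:
    def test_output_dimension_is_three_per_oscillator(self, rng):
        A = random_adjacency(5, 6, rng)
        s = simulate_coupled_lorenz(A, A, None, 50, seed=2)
        assert s.q == 15

    def test_zero_coupling_decouples_from_topology(self, rng):
        # with c=0 the trajectory is independent of the adjacency matrix
        A1 = random_adjacency(5, 6, rng)
        A2 = random_adjacency(5, 10, rng)
        init = rng.uniform(-10, 10, size=(3, 5))
        h = rng.uniform(-0.2, 0.2, size=5)
        a = simulate_coupled_lorenz(A1, A1, None, 80, c=0.0, h=h, init=init)
        b = simulate_coupled_lorenz(A2, A2, None, 80, c=0.0, h=h, init=init)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_zero_coupling_matches_single_oscillators(self, rng):
        # each oscillator follows its own Lorenz flow with rho = 28 (1 + h_k)
        A = random_adjacency(3, 2, rng)
        init = rng.uniform(-5, 5, size=(3, 3))
        h = np.array([-0.1, 0.0, 0.15])
        coupled = simulate_coupled_lorenz(A, A, None, 40, c=0.0, h=h,
                                          init=init, dt=0.002, sample_every=6)
        for k in range(3):
            solo = simulate_lorenz63_switch(
                10.0, 10.0, None, 235, dt=0.002, rho=28 * (1 + h[k]),
                init=init[:, k])
            # coupled output is sampled every 6 integrator steps
            assert np.allclose(coupled.values[:, 3 * k:3 * k + 3],
                               solo.values[::6][:40], atol=1e-8)

    def test_structural_truth_recorded(self, rng):
        A = random_adjacency(5, 6, rng)
        B = rewire_random(A, rng)
        s = simulate_coupled_lorenz(A, B, 100, 300, seed=3)
        assert np.array_equal(s.truth.before, A)
        assert np.array_equal(s.truth.after, B)

    def test_non_binary_adjacency_rejected(self):
        A = np.full((3, 3), 0.5)
        with pytest.raises(ValueError):
            simulate_coupled_lorenz(A, A, None, 10)


class TestAdjacencyChanges:
    def test_rewire_preserves_edge_count_and_differs(self, rng):
        A = random_adjacency(5, 6, rng)
        B = rewire_random(A, rng)
        assert B.sum() == A.sum()
        assert not np.array_equal(A, B)
        assert not np.diag(B).any()

    def test_densify_adds_exactly_k_edges(self, rng):
        A = random_adjacency(5, 6, rng)
        B = densify(A, 8, rng)
        assert B.sum() == A.sum() + 8
        assert ((B - A) >= 0).all()  # only additions
        assert not np.diag(B).any()

    def test_densify_beyond_complete_graph_rejected(self, rng):
        A = random_adjacency(3, 4, rng)
        with pytest.raises(ValueError):
            densify(A, 5, rng)

    def test_rewire_needs_edges_and_nodes(self, rng):
        with pytest.raises(ValueError):
            rewire_random(np.zeros((5, 5), dtype=int), rng)


class TestKuramotoSivashinsky:
    def test_zero_forcing_zero_field_is_fixed_point(self):
        s = simulate_ks_switch(0.0, 0.0, None, 20, init=np.zeros(128),
                               transient=0.0)
        assert np.abs(s.values).max() < 1e-12

    def test_output_shape_matches_grid(self):
        s = simulate_ks_switch(0.4, -0.2, 30, 60, seed=5, transient=5.0)
        assert s.values.shape == (60, 128)

    def test_etdrk4_step_halving_agreement(self):
        x = 60.0 * np.arange(128) / 128
        init = 0.5 * np.cos(2 * np.pi * x / 12)
        a = simulate_ks_switch(0.3, 0.3, None, 26, dt=0.01, transient=0.0,
                               init=init)
        b = simulate_ks_switch(0.3, 0.3, None, 51, dt=0.005, transient=0.0,
                               init=init)
        rel = (np.linalg.norm(a.values[25] - b.values[50])
               / np.linalg.norm(b.values[50]))
        assert rel < 1e-4

    def test_forcing_wavelength_must_divide_domain(self):
        with pytest.raises(ValueError):
            simulate_ks_switch(0.2, 0.4, 10, 30, lam=11.0)

    def test_mu_actually_switches_at_t_p(self):
        s = simulate_ks_switch(0.8, -0.8, 15, 40, seed=6, transient=10.0)
        ref = simulate_ks_switch(0.8, 0.8, None, 40, seed=6, transient=10.0)
        tp = s.truth.t_p
        assert np.allclose(s.values[:tp + 1], ref.values[:tp + 1], atol=1e-10)
        assert np.abs(s.values[-1] - ref.values[-1]).max() > 1e-3


class TestChannelsAndNoise:
    def test_subsample_keeps_equally_spaced_channels(self, rng):
        s = MultivariateSeries(values=rng.normal(size=(10, 128)), dt=1.0)
        sub = subsample_channels(s, 32)
        assert sub.q == 32
        assert np.array_equal(sub.values, s.values[:, ::4])

    def test_subsample_identity_and_truth_passthrough(self, rng):
        from rctip.systems import Truth
        s = MultivariateSeries(values=rng.normal(size=(10, 8)), dt=1.0,
                               truth=Truth(t_p=5, delta_h=1.0))
        sub = subsample_channels(s, 8)
        assert np.array_equal(sub.values, s.values)
        assert sub.truth == s.truth

    def test_subsample_non_divisor_rejected(self, rng):
        s = MultivariateSeries(values=rng.normal(size=(10, 9)), dt=1.0)
        with pytest.raises(ValueError):
            subsample_channels(s, 4)

    def test_zero_noise_is_identity(self, rng):
        s = MultivariateSeries(values=rng.normal(size=(50, 3)), dt=1.0)
        assert add_observation_noise(s, 0.0, 1) is s

    def test_noise_moments(self, rng):
        s = MultivariateSeries(values=np.zeros((40000, 3)), dt=1.0)
        noisy = add_observation_noise(s, 0.7, 11)
        sd = (noisy.values - s.values).std()
        assert abs(sd - 0.7) < 0.05 * 0.7

    def test_noise_seeded(self, rng):
        s = MultivariateSeries(values=np.zeros((20, 2)), dt=1.0)
        a = add_observation_noise(s, 1.0, 42)
        b = add_observation_noise(s, 1.0, 42)
        assert np.array_equal(a.values, b.values)

    def test_negative_noise_rejected(self, rng):
        s = MultivariateSeries(values=np.zeros((5, 2)), dt=1.0)
        with pytest.raises(ValueError):
            add_observation_noise(s, -0.1, 0)


class TestBenchmarkFactory:
    def test_run_count_and_placement_bands(self):
        spec = BenchmarkSpec("lorenz63", 10, "train", 1000, T_w=300, seed=5)
        runs = make_benchmark(spec)
        assert len(runs) == 10
        assert all(350 <= r.t_p <= 700 for r in runs)
        test_spec = BenchmarkSpec("lorenz63", 10, "test", 5000, T_w=300, seed=5)
        assert all(600 <= r.t_p <= 4400 for r in make_benchmark(test_spec))

    def test_train_runs_have_study_length(self):
        runs = make_benchmark(BenchmarkSpec("lorenz63", 3, "train", 1000, seed=1))
        assert all(r.series.T == 1000 for r in runs)

    def test_distinct_runs_distinct_trajectories(self):
        runs = make_benchmark(BenchmarkSpec("lorenz63", 5, "train", 1000, seed=2))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.array_equal(runs[i].series.values,
                                          runs[j].series.values)

    def test_batch_regenerates_exactly(self):
        spec = BenchmarkSpec("lorenz63", 4, "train", 800, seed=77, noise_sd=0.3)
        a = make_benchmark(spec)
        b = make_benchmark(spec)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.series.values, rb.series.values)
            assert ra.t_p == rb.t_p

    def test_batch_matches_single_run_integration(self):
        # the vectorized generator reproduces the reference simulator
        spec = BenchmarkSpec("lorenz63", 3, "train", 800, seed=9)
        runs = make_benchmark(spec)
        root = np.random.SeedSequence(9)
        for run, ss in zip(runs, root.spawn(3)):
            rng = np.random.default_rng(ss)
            int(rng.integers(350, 501))
            s1, s2 = rng.uniform(5, 15, size=2)
            ref = simulate_lorenz63_switch(s1, s2, run.t_p, 800,
                                           seed=ss.spawn(1)[0])
            assert np.allclose(ref.values, run.series.values, atol=1e-8)

    def test_fixed_sigma_delta_option(self):
        runs = make_benchmark(BenchmarkSpec(
            "lorenz63", 6, "train", 1000, seed=3,
            options={"sigma_delta": 3.0}))
        for r in runs:
            assert abs(abs(r.delta_h) - 3.0) < 1e-12

    def test_ks_runs_are_channel_subsampled(self):
        runs = make_benchmark(BenchmarkSpec("ks", 2, "train", 700, seed=4))
        assert all(r.series.q == 32 for r in runs)

    def test_coupled_truth_allows_reintegration(self):
        # the recorded (A, h, init) reproduce each half of the trajectory
        runs = make_benchmark(BenchmarkSpec(
            "coupled_lorenz", 1, "train", 700, seed=8))
        run = runs[0]
        tr = run.series.truth
        init = run.series.values[0].reshape(5, 3).T
        ref = simulate_coupled_lorenz(tr.before, tr.before, None, 700,
                                      c=tr.params["c"], h=tr.params["h"],
                                      init=init)
        tp = run.t_p
        assert np.allclose(run.series.values[:tp + 1], ref.values[:tp + 1],
                           atol=1e-6)
        assert np.abs(run.series.values[-1] - ref.values[-1]).max() > 1e-3

    def test_invalid_role_band(self):
        with pytest.raises(ValueError):
            make_benchmark(BenchmarkSpec("lorenz63", 2, "train", 500, seed=0))
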