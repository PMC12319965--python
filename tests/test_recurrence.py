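import numpy as np
import pytest

from insideout.containers import EnvelopeEpochs
from insideout.irreversibility import corr_matrices
from insideout.recurrence import (
    build_embedding,
    coherent_phase_surrogate,
    dataset_recurrence_rate,
    fnn_counts,
    fnn_dimension,
    mi_delay,
    recurrence_network,
    sliding_metric,
)


class TestSlidingMetric:
    def test_window_count_and_starts(self, rng):
        """2-s epochs, 1-s windows, 80% overlap: six windows at 0, .2 ... 1.0 s."""
        env = EnvelopeEpochs(
            np.abs(rng.standard_normal((2, 4, 400))), 200.0, epoch_length_s=2.0
        )
        ts = sliding_metric(env, "irreversibility", tau=3)
        assert ts.values.size == 12  # 6 windows per epoch
        starts = ts.times[ts.epoch_index == 0]
        assert np.allclose(starts, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

    def test_identical_epochs_identical_blocks(self, rng):
        epoch = np.abs(rng.standard_normal((1, 4, 400)))
        env = EnvelopeEpochs(np.repeat(epoch, 3, axis=0), 200.0, epoch_length_s=2.0)
        ts = sliding_metric(env, "coherence", tau=3)
        blocks = ts.values.reshape(3, -1)
        assert np.allclose(blocks[0], blocks[1])
        assert np.allclose(blocks[0], blocks[2])

    def test_window_variance_shrinks_with_window_length(self, rng):
        env = EnvelopeEpochs(
            np.abs(rng.standard_normal((4, 4, 600))) + 0.5, 200.0,
            epoch_length_s=3.0,
        )
        short = sliding_metric(env, "irreversibility", tau=2, window_s=0.5)
        longer = sliding_metric(env, "irreversibility", tau=2, window_s=2.0)
        assert longer.values.std() < short.values.std()

    def test_window_longer_than_epoch_rejected(self, small_env):
        with pytest.raises(ValueError, match="longer than epoch"):
            sliding_metric(small_env, "irreversibility", tau=2, window_s=5.0)


class TestMiDelay:
    def test_sine_first_minimum_near_quarter_period(self):
        for period in (20, 28):
            x = np.sin(2 * np.pi * np.arange(400) / period)
            assert abs(mi_delay(x, max_delay=50) - period / 4) <= 1

    def test_self_information_is_maximum_of_scan(self, rng):
        from insideout.recurrence import _hist_mi

        x = rng.standard_normal(300)
        mi0 = _hist_mi(x, x, 10)
        scanned = [_hist_mi(x[:-t], x[t:], 10) for t in range(1, 50)]
        assert mi0 > max(scanned)

    def test_no_local_minimum_falls_back_with_warning(self):
        # a one-lag scan has no interior point, so no local minimum exists
        # and the argmin fallback must fire
        x = np.random.default_rng(5).standard_normal(64)
        with pytest.warns(UserWarning, match="argmin"):
            tau = mi_delay(x, max_delay=1)
        assert tau == 1

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mi_delay(np.ones(50))


class TestFnnDimension:
    def test_ramp_has_no_false_neighbours_at_m1(self):
        assert fnn_dimension(np.arange(80.0), tau=1, m_max=5) == 1

    def test_white_noise_counts_non_increasing(self):
        x = np.random.default_rng(0).standard_normal(400)
        counts, _ = fnn_counts(x, tau=1, m_max=8)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_lorenz_bulk_resolved_by_m3(self):
        """Most false neighbours of the Lorenz attractor vanish by dimension 3."""
        from scipy.integrate import solve_ivp

        def lorenz(t, s):
            x, y, z = s
            return [10 * (y - x), x * (28 - z) - y, x * y - 8 / 3 * z]

        sol = solve_ivp(
            lorenz, [0, 50], [1.0, 1.0, 1.0],
            t_eval=np.arange(0, 50, 0.01), rtol=1e-8,
        )
        xs = sol.y[0][1000:]
        tau = 2
        counts, fractions = fnn_counts(xs, tau, m_max=6)
        assert fractions[0] > 0.9  # one dimension: nearly all false
        assert fractions[2] < 0.1  # resolved by m = 3
        assert fractions[2] < 0.1 * fractions[0]
        # plateau selector picks a small dimension
        assert fnn_dimension(xs, tau, m_max=6, tol=0.1) <= 3


class TestRecurrenceNetwork:
    def test_three_point_worked_example(self):
        net = recurrence_network(np.array([0.0, 1.0, 10.0]))
        assert net.epsilon == pytest.approx(9.0)
        assert net.recurrence_rate == pytest.approx(2 / 3)
        assert net.adjacency[0, 1] == 1 and net.adjacency[1, 2] == 1
        assert net.adjacency[0, 2] == 0

    def test_constant_series_full_graph(self):
        net = recurrence_network(np.zeros((6, 2)))
        assert net.epsilon == 0.0
        assert net.recurrence_rate == 1.0

    def test_threshold_matches_bruteforce_heaviside(self, rng):
        pts = rng.standard_normal((30, 3))
        net = recurrence_network(pts)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        brute = ((net.epsilon - D) >= 0).astype(int)
        np.fill_diagonal(brute, 0)
        assert np.array_equal(net.adjacency, brute)

    def test_epsilon_is_minimal(self, rng):
        """Dropping the longest admitted edges disconnects the graph."""
        import scipy.sparse
        import scipy.sparse.csgraph

        pts = rng.standard_normal((25, 2))
        net = recurrence_network(pts)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        smaller = ((D <= net.epsilon) & (D < net.epsilon)) & ~np.eye(25, dtype=bool)
        n_comp, _ = scipy.sparse.csgraph.connected_components(
            scipy.sparse.csr_matrix(smaller), directed=False
        )
        assert n_comp > 1

    def test_periodic_beats_amplitude_matched_noise(self):
        """Exactly revisited orbits give denser recurrence networks than noise."""
        rrs_per, rrs_wn = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            t = np.arange(400)
            per = np.sin(2 * np.pi * t / 8 + r.random() * 2 * np.pi)
            wn = r.standard_normal(400) * per.std()
            for x, out in [(per, rrs_per), (wn, rrs_wn)]:
                tau = mi_delay(x, max_delay=50)
                m = fnn_dimension(x, tau, m_max=6)
                out.append(
                    recurrence_network(build_embedding(x, tau, m)).recurrence_rate
                )
        assert np.median(rrs_per) > np.median(rrs_wn)


class TestCoherentPhaseSurrogate:
    def test_common_phase_preserves_circular_cross_correlations(self, small_env):
        sur = coherent_phase_surrogate(small_env, "common_phase", seed=3)
        n = small_env.n_samples
        for e in range(small_env.n_epochs):
            Fa = np.fft.rfft(small_env.values[e], axis=1)
            Fb = np.fft.rfft(sur.values[e], axis=1)
            ca = np.fft.irfft(np.conj(Fa[:, None]) * Fa[None, :], n=n, axis=2)
            cb = np.fft.irfft(np.conj(Fb[:, None]) * Fb[None, :], n=n, axis=2)
            assert np.max(np.abs(ca - cb)) < 1e-10 * np.max(np.abs(ca))

    def test_surrogate_differs_from_original(self, small_env):
        sur = coherent_phase_surrogate(small_env, "common_phase", seed=3)
        assert np.max(np.abs(sur.values - small_env.values)) > 0

    def test_circular_irreversibility_invariant(self, small_env):
        """r built on circular lagged correlations is a cross-spectral
        functional, so a common-phase surrogate cannot change it."""
        sur = coherent_phase_surrogate(small_env, "common_phase", seed=4)
        for tau in (1, 5, 20):
            for e in range(small_env.n_epochs):
                Xa = small_env.values[e] - small_env.values[e].mean(1, keepdims=True)
                Xb = sur.values[e] - sur.values[e].mean(1, keepdims=True)
                Ca = corr_matrices(Xa, tau, circular=True).Cf
                Cb = corr_matrices(Xb, tau, circular=True).Cf
                assert np.max(np.abs(Ca - Cb)) < 1e-8

    def test_cholesky_csd_runs_and_matches_scale(self, small_env):
        sur = coherent_phase_surrogate(small_env, "cholesky_csd", seed=5)
        assert np.all(np.isfinite(sur.values))
        assert sur.values.std() == pytest.approx(small_env.values.std(), rel=0.2)

    def test_surrogate_lowers_rr_of_recurrent_series(self):
        """Static null: phase randomization reduces the recurrence rate of a
        deterministic, strongly recurrent metric timeseries."""
        fs = 100.0
        t = np.arange(2000) / fs
        chans = np.stack(
            [
                2.0 + np.sin(2 * np.pi * 0.9 * t + p)
                + 0.4 * np.sin(2 * np.pi * 3.7 * t + 2 * p)
                for p in (0.0, 1.1, 2.3)
            ]
        )
        env = EnvelopeEpochs(
            chans.reshape(3, 2, 1000).transpose(1, 0, 2), fs, epoch_length_s=10.0
        )

        def rr(e):
            return dataset_recurrence_rate(
                e, "irreversibility", tau=3, percentile=80.0, m_max=6
            )

        r0 = rr(env)
        rs = [
            rr(coherent_phase_surrogate(env, "common_phase", seed=s))
            for s in range(20)
        ]
        assert np.median(rs) < r0


def test_dynamics_compare_fixed_seed_reproducible(mini_cohort):
    from insideout.recurrence import dynamics_compare

    datasets, design = mini_cohort
    sub = {
        k: v for k, v in datasets.items()
        if k[0] in design.participant_ids[:4] and k[2] == "Open"
    }
    sub_design = type(design)(
        design.participant_ids[:4], design.drug_levels, ("Open",)
    )
    df1, p1 = dynamics_compare(
        sub, sub_design, tau=3, n_perm=100, seed=11, m_max=4
    )
    df2, p2 = dynamics_compare(
        sub, sub_design, tau=3, n_perm=100, seed=11, m_max=4
    )
    assert df1.equals(df2)
    assert p1 == p2
    assert set(p1) == {("Open", "rr_true"), ("Open", "rr_surrogate")}
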