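import numpy as np
import pytest
from scipy import integrate

from eghr import (
    MixingModel,
    NetworkState,
    TrainConfig,
    bss_error,
    default_E0,
    eghr_cost,
    eghr_step,
    global_factor,
    init_network,
    laplace_sampler,
    make_fixture,
    outputs,
    sample_mixing_matrix,
    train_eghr,
)

LN2 = np.log(2.0)


class TestOutputs:
    def test_identity(self):
        np.testing.assert_array_equal(
            outputs(np.eye(2), np.array([3.0, -1.0])), [3.0, -1.0]
        )

    def test_hand_example(self):
        W = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        np.testing.assert_array_equal(outputs(W, np.array([1.0, 2.0, 3.0])), [3.0, 3.0])

    def test_batch_shape(self, rng):
        assert outputs(rng.normal(size=(2, 6)), rng.normal(size=(6, 50))).shape == (2, 50)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            outputs(np.eye(2), np.ones(3))


class TestGlobalFactor:
    def test_at_zero(self, laplace):
        assert global_factor(np.zeros(2), laplace) == pytest.approx(LN2)

    def test_unit_outputs(self, laplace):
        assert global_factor(np.array([1.0, -1.0]), laplace) == pytest.approx(
            2 * np.sqrt(2) + LN2
        )

    def test_additivity(self, laplace):
        a = 0.73
        assert global_factor(np.array([a, a]), laplace) == pytest.approx(
            2 * global_factor(np.array([a]), laplace)
        )


class TestDefaultE0:
    def test_two_sources(self, laplace):
        assert default_E0(laplace, 2) == pytest.approx(3 + LN2)

    def test_ten_sources(self, laplace):
        assert default_E0(laplace, 10) == pytest.approx(11 + 5 * LN2)

    def test_empty_sum(self, laplace):
        assert default_E0(laplace, 0) == 1.0

    def test_matches_numeric_entropy_integral(self, laplace):
        # independent oracle: <-log p0(s)> under the unit Laplace density
        p = lambda s: np.exp(-np.sqrt(2) * np.abs(s)) / np.sqrt(2)
        val, _ = integrate.quad(lambda s: -np.log(p(s)) * p(s), -30, 30)
        assert default_E0(laplace, 2) == pytest.approx(2 * val + 1, abs=1e-8)

    def test_missing_entropy_instructs_fallback(self, laplace):
        from dataclasses import replace

        broken = replace(laplace, per_unit_entropy=None)
        with pytest.raises(ValueError, match="Monte Carlo"):
            default_E0(broken, 2)


class TestCost:
    def test_zero_at_threshold(self, laplace):
        U = np.zeros((2, 5))
        E0 = global_factor(np.zeros(2), laplace)
        assert eghr_cost(U, laplace, E0) == 0.0

    def test_single_column_offset(self, laplace):
        u = np.array([[1.0], [0.0]])
        e = global_factor(u[:, 0], laplace)
        assert eghr_cost(u, laplace, e - 2.0) == pytest.approx(2.0)

    def test_two_column_average(self, laplace):
        # columns with E - E0 = 1 and 3 give (1 + 9)/4
        u1 = np.array([1.0, 0.0])
        u2 = np.array([3.0, 0.0])
        e1 = global_factor(u1 / np.sqrt(2), laplace)  # any values; use offsets
        U = np.column_stack([u1 / np.sqrt(2), u2 / np.sqrt(2)])
        E0 = e1 - 1.0  # first column offset exactly 1; second is e1+2-E0 = 3
        assert eghr_cost(U, laplace, E0) == pytest.approx(2.5)


class TestEghrStep:
    def test_zero_gate_freezes_weights(self, laplace):
        W = np.eye(2)
        x = np.zeros((2, 1))
        E0 = global_factor(np.zeros(2), laplace)  # E(u) = E0 exactly
        np.testing.assert_array_equal(eghr_step(W, x, laplace, E0, 0.5), W)

    def test_hand_computed_update(self, laplace):
        W = np.eye(2)
        x = np.array([[1.0], [-1.0]])
        E0 = 3 + LN2
        W2 = eghr_step(W, x, laplace, E0, 1.0)
        expected = (3 - 2 * np.sqrt(2)) * np.sqrt(2) * np.array(
            [[1.0, -1.0], [-1.0, 1.0]]
        )
        np.testing.assert_allclose(W2 - W, expected, atol=1e-12)
        assert expected[0, 0] == pytest.approx(0.24264, abs=1e-5)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_finite_difference_gradient(self, laplace, trial):
        rng = np.random.default_rng(trial)
        n_u, n_x, batch = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 9)
        W = rng.normal(size=(n_u, n_x))
        X = rng.normal(size=(n_x, batch))
        E0 = float(rng.uniform(0, 4))
        step = eghr_step(W, X, laplace, E0, 1.0) - W
        h = 1e-6
        num = np.zeros_like(W)
        for i in range(n_u):
            for j in range(n_x):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += h
                Wm[i, j] -= h
                num[i, j] = (
                    eghr_cost(Wp @ X, laplace, E0) - eghr_cost(Wm @ X, laplace, E0)
                ) / (2 * h)
        scale = max(np.abs(num).max(), 1e-12)
        assert np.abs(step + num).max() / scale < 1e-5

    def test_nonfinite_update_raises(self, laplace):
        with np.errstate(over="ignore"), pytest.raises(FloatingPointError):
            eghr_step(np.array([[1e308]]), np.array([[1e10]]), laplace, 0.0, 1e300)


class TestInitNetwork:
    def test_reproducible(self):
        np.testing.assert_array_equal(
            init_network(2, 6, seed=5).W, init_network(2, 6, seed=5).W
        )

    def test_shape(self):
        assert init_network(2, 6, seed=0, scale=0.1).W.shape == (2, 6)

    def test_zero_scale_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            net = init_network(2, 3, seed=0, scale=0.0)
        assert not net.W.any()

    def test_overcomplete_warns(self):
        with pytest.warns(UserWarning, match="overcomplete"):
            init_network(5, 3, seed=0)


class TestTraining:
    def test_zero_learning_rate_is_identity(self, laplace):
        fx = make_fixture("tiny_single_context", seed=2)
        cfg = TrainConfig(eta=0.0, batch_size=50, n_steps=20, record_every=10)
        final, _ = train_eghr(
            fx["net"], fx["sampler"], fx["mixing"], None, laplace, cfg
        )
        np.testing.assert_array_equal(final.W, fx["net"].W)

    def test_single_context_recovers_permutation(self, laplace):
        fx = make_fixture("tiny_single_context", seed=3)
        final, traj = train_eghr(
            fx["net"], fx["sampler"], fx["mixing"], None, laplace, fx["cfg"]
        )
        K = final.W @ fx["mixing"].matrices[0]
        # |K| close to a permutation matrix: one entry near 1 per row/col
        dom = np.sort(np.abs(K).ravel())[::-1]
        assert dom[0] == pytest.approx(1.0, abs=0.1)
        assert dom[1] == pytest.approx(1.0, abs=0.1)
        assert dom[2] < 0.1
        assert bss_error(K).total < 0.1

    def test_output_scale_calibrated_to_sources(self, laplace, rng):
        # after convergence with the default E0, output variance matches
        # the unit source variance
        fx = make_fixture("tiny_single_context", seed=4)
        final, _ = train_eghr(
            fx["net"], fx["sampler"], fx["mixing"], None, laplace, fx["cfg"]
        )
        s = laplace_sampler(2)(50_000, rng)
        u = final.W @ (fx["mixing"].matrices[0] @ s)
        np.testing.assert_allclose(u.var(axis=1), 1.0, rtol=0.1)

    def test_two_context_learning_and_cost_decrease(self, laplace):
        fx = make_fixture("tiny_two_context", seed=0)
        final, traj = train_eghr(
            fx["net"], fx["sampler"], fx["mixing"], fx["schedule"], laplace, fx["cfg"]
        )
        assert traj.bss_error_per_context[-1].max() < 0.1
        assert np.all(traj.cost >= 0.0)
        # cost decreases in coarse moving average over the run
        mid = len(traj.cost) // 2
        assert traj.cost[mid:].mean() < traj.cost[:mid].mean()

    def test_divergence_aborts_with_diagnostic(self, laplace):
        fx = make_fixture("tiny_single_context", seed=5)
        cfg = TrainConfig(eta=50.0, batch_size=20, n_steps=2000, record_every=2000)
        with pytest.raises(FloatingPointError):
            train_eghr(fx["net"], fx["sampler"], fx["mixing"], None, laplace, cfg)

    def test_trajectory_series_aligned(self, laplace):
        fx = make_fixture("tiny_single_context", seed=6)
        _, traj = train_eghr(
            fx["net"], fx["sampler"], fx["mixing"], None, laplace, fx["cfg"]
        )
        n = len(traj.times)
        assert traj.cost.shape == (n,)
        assert traj.bss_error_per_context.shape[0] == n
        assert traj.overlaps.shape[0] == n
        assert traj.W_snapshots.shape[0] == n
        assert traj.times[0] == 0  # untrained state is recorded
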