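import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eghr import (
    MixingModel,
    context_vector_mixing,
    make_context_schedule,
    markov_switching_omega,
    mix,
    ou_matrix_process,
    rotation_matrix,
    sample_laplace_sources,
    sample_mixing_matrix,
    time_varying_mixing,
    zero_sum_context_components,
)


class TestSampleMixingMatrix:
    def test_shape_and_rank(self):
        a = sample_mixing_matrix(6, 2, seed=3)
        assert a.shape == (6, 2)
        assert np.linalg.matrix_rank(a) == 2

    def test_large_undercomplete_matrix(self):
        a = sample_mixing_matrix(2000, 10, seed=0)
        assert a.shape == (2000, 10)
        assert np.linalg.matrix_rank(a) == 10

    def test_reproducible(self):
        np.testing.assert_array_equal(
            sample_mixing_matrix(5, 3, seed=9), sample_mixing_matrix(5, 3, seed=9)
        )

    def test_rejects_overcomplete(self):
        with pytest.raises(ValueError, match="n_x >= n_s"):
            sample_mixing_matrix(2, 3, seed=0)


class TestContextSchedule:
    def test_alternating_cycles(self):
        sch = make_context_schedule(2, 4, 100, mode="alternating")
        assert list(sch.context_of_session) == [1, 2, 1, 2]

    def test_uniform_random_covers_range(self):
        sch = make_context_schedule(100, 600, 10**5, mode="uniform_random", seed=0)
        assert sch.n_sessions == 600
        assert sch.context_of_session.min() >= 1
        assert sch.context_of_session.max() <= 100

    def test_single_context(self):
        sch = make_context_schedule(1, 3, 10, mode="alternating")
        assert list(sch.context_of_session) == [1, 1, 1]

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            make_context_schedule(2, 4, 10, mode="shuffled")

    def test_context_at_step_respects_session_length(self):
        sch = make_context_schedule(2, 4, 10, mode="alternating")
        assert sch.context_at_step(0) == 1
        assert sch.context_at_step(9) == 1
        assert sch.context_at_step(10) == 2


class TestRotationMatrix:
    def test_zero_angle_is_identity(self):
        np.testing.assert_allclose(rotation_matrix(0.0), np.eye(2))

    def test_quarter_turn(self):
        np.testing.assert_allclose(
            rotation_matrix(np.pi / 2), [[0, -1], [1, 0]], atol=1e-15
        )

    def test_orthogonal_along_trajectory(self):
        for t in range(0, 500, 37):
            r = rotation_matrix(np.sqrt(2) * np.pi / 100 * t)
            np.testing.assert_allclose(r.T @ r, np.eye(2), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0)


class TestOuProcess:
    def test_stationary_variance(self):
        r = ou_matrix_process(1, 1, tau=1e-3, n_steps=400_000, dt=5e-5, seed=0)
        assert r[:, 0, 0].var() == pytest.approx(1.0, abs=0.05)

    def test_autocorrelation_decay(self):
        tau, dt = 1e-3, 5e-5
        x = ou_matrix_process(1, 1, tau=tau, n_steps=400_000, dt=dt, seed=1)[:, 0, 0]
        x = x - x.mean()
        for k in (5, 10, 20):
            rho = np.dot(x[:-k], x[k:]) / np.dot(x, x)
            # Euler-Maruyama decay (1 - dt/tau)^k approximates exp(-k dt/tau)
            assert rho == pytest.approx(np.exp(-k * dt / tau), abs=0.04)

    def test_reproducible(self):
        a = ou_matrix_process(2, 2, 1e-3, 50, 1e-5, seed=3)
        b = ou_matrix_process(2, 2, 1e-3, 50, 1e-5, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_unstable_discretisation_rejected(self):
        with pytest.raises(ValueError, match="dt < tau"):
            ou_matrix_process(1, 1, tau=1e-3, n_steps=10, dt=1e-3, seed=0)


class TestMarkovSwitching:
    def test_no_switching_is_constant(self):
        seq = markov_switching_omega(1000, p_switch=0.0, seed=4)
        assert np.unique(seq).size == 1

    def test_degenerate_single_value(self):
        seq = markov_switching_omega(100, omegas=[0.0], p_switch=1.0, seed=0)
        np.testing.assert_array_equal(seq, 0.0)

    def test_switch_count_near_expectation(self):
        n, p = 10**6, 1.0 / 8820.0
        seq = markov_switching_omega(n, p_switch=p, seed=7)
        # value changes underestimate redraws (a redraw may repeat the
        # value); 2/3 of uniform redraws from 3 values change it
        changes = np.sum(seq[1:] != seq[:-1])
        expected = n * p * 2 / 3
        assert abs(changes - expected) < 3 * np.sqrt(n * p)

    def test_values_come_from_default_set(self):
        seq = markov_switching_omega(1000, p_switch=0.5, seed=2)
        assert set(np.unique(seq)) <= {-0.1 * np.pi, 0.0, 0.1 * np.pi}

    def test_empty_omegas_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            markov_switching_omega(10, omegas=[], p_switch=0.1, seed=0)


class TestTimeVaryingMixing:
    def test_zero_r_reduces_to_a0(self, rng):
        a0 = rng.normal(size=(6, 2))
        a1 = rng.normal(size=(6, 2))
        model = time_varying_mixing(a0, a1, np.zeros((5, 2, 2)))
        np.testing.assert_allclose(model.matrix_at(3), a0)

    def test_identity_r_adds_components(self, rng):
        a0, a1 = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        model = time_varying_mixing(a0, a1, np.broadcast_to(np.eye(2), (4, 2, 2)))
        np.testing.assert_allclose(model.matrix_at(0), a0 + a1)

    def test_rotation_trajectory_shapes(self, rng):
        a0, a1 = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        r_traj = np.stack([rotation_matrix(0.1 * t) for t in range(10)])
        model = time_varying_mixing(a0, a1, r_traj)
        assert model.matrix_at(7).shape == (6, 2)

    def test_incompatible_shapes_rejected(self, rng):
        with pytest.raises(ValueError, match="incompatible"):
            time_varying_mixing(
                rng.normal(size=(6, 2)), rng.normal(size=(6, 3)),
                np.zeros((5, 2, 2)),
            )

    def test_frozen_r_equals_static_mixing(self, rng):
        a0, a1 = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        r = rotation_matrix(0.7)
        model = time_varying_mixing(a0, a1, np.broadcast_to(r, (20, 2, 2)).copy())
        s = sample_laplace_sources(2, 20, seed=0)
        static = MixingModel(kind="static", matrices=(a0 + a1 @ r,))
        np.testing.assert_allclose(mix(model, s), mix(static, s), atol=1e-12)


class TestContextVectorMixing:
    def test_zero_vector_gives_a0(self, rng):
        a0 = rng.normal(size=(4, 2))
        deps = [rng.normal(size=(4, 2)) for _ in range(3)]
        np.testing.assert_array_equal(
            context_vector_mixing(a0, deps, [0, 0, 0]), a0
        )

    def test_basis_vector_recovers_hat_matrix(self):
        comps = zero_sum_context_components(10, 3, seed=5)
        a0, deps = comps[0], comps[1:]
        # A(k) = hat-A(k) - A0, so v = e_k gives exactly hat-A(k)
        a_v = context_vector_mixing(a0, deps, [1, 0, 0, 0])
        np.testing.assert_allclose(a_v, deps[0] + a0)

    def test_uniform_vector_recovers_a0(self):
        comps = zero_sum_context_components(10, 3, seed=6)
        a0, deps = comps[0], comps[1:]
        a_v = context_vector_mixing(a0, deps, [0.25] * 4)
        np.testing.assert_allclose(a_v, a0, atol=1e-13)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            context_vector_mixing(
                rng.normal(size=(4, 2)), [rng.normal(size=(4, 2))], [1.0, 2.0]
            )


class TestZeroSumComponents:
    def test_components_sum_to_zero(self):
        comps = zero_sum_context_components(100, 10, seed=1)
        assert max(np.abs(sum(comps[1:])).max(), 0) < 1e-12
        assert all(c.shape == (100, 10) for c in comps)

    def test_a0_full_column_rank(self):
        a0 = zero_sum_context_components(100, 10, seed=2)[0]
        assert np.linalg.matrix_rank(a0) == 10

    def test_rejects_overcomplete(self):
        with pytest.raises(ValueError):
            zero_sum_context_components(3, 10, seed=0)


class TestMix:
    def test_static_identity_passthrough(self):
        s = sample_laplace_sources(3, 10, seed=0)
        model = MixingModel(kind="static", matrices=(np.eye(3),))
        np.testing.assert_array_equal(mix(model, s), s.values)

    def test_single_source_fanout(self):
        model = MixingModel(kind="static", matrices=(np.array([[1.0], [1.0]]),))
        x = mix(model, np.array([[3.0]]))
        np.testing.assert_array_equal(x, [[3.0], [3.0]])

    def test_per_context_block_structure(self, rng):
        mats = (rng.normal(size=(4, 2)), rng.normal(size=(4, 2)))
        model = MixingModel(kind="per_context", matrices=mats)
        sch = make_context_schedule(2, 4, 5, mode="alternating")
        s = sample_laplace_sources(2, 20, seed=1)
        x = mix(model, s, sch)
        for session in range(4):
            sl = slice(5 * session, 5 * (session + 1))
            np.testing.assert_allclose(
                x[:, sl], mats[session % 2] @ s.values[:, sl]
            )

    def test_per_context_requires_schedule(self, rng):
        model = MixingModel(
            kind="per_context",
            matrices=(rng.normal(size=(4, 2)), rng.normal(size=(4, 2))),
        )
        with pytest.raises(ValueError, match="Schedule"):
            mix(model, sample_laplace_sources(2, 10, seed=0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(alpha=st.floats(-3, 3), beta=st.floats(-3, 3), seed=st.integers(0, 100))
    def test_linearity_in_sources(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        model = MixingModel(kind="static", matrices=(rng.normal(size=(5, 3)),))
        s1 = rng.normal(size=(3, 7))
        s2 = rng.normal(size=(3, 7))
        np.testing.assert_allclose(
            mix(model, alpha * s1 + beta * s2),
            alpha * mix(model, s1) + beta * mix(model, s2),
            atol=1e-9,
        )
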