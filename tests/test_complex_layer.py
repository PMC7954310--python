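"""Complex-cell pooling and the modified BCM / NBCM plasticity rules."""

from dataclasses import replace

import numpy as np
import pytest

from v1complex import complex_layer as cl
from v1complex.complex_layer import (ComplexConnectome, ComplexTrainConfig,
                                     average_frame_input, complex_response,
                                     init_complex_connectome,
                                     mean_pairwise_cosine,
                                     normalize_responses,
                                     recruited_simple_cells,
                                     substantial_patterns, update_bcm,
                                     update_nbcm)


def toy_connectome(A, theta, **kw):
    return ComplexConnectome(A_SC=np.asarray(A, dtype=float),
                             theta=np.asarray(theta, dtype=float), **kw)


class TestFrameAveraging:
    def test_single_frame_unit_scale_passthrough(self):
        r = np.array([0.1, 0.5, 2.0])
        np.testing.assert_array_equal(average_frame_input([r], 1.0), r)

    def test_hand_mean_of_15_frames(self):
        frames = np.arange(15 * 3, dtype=float).reshape(15, 3)
        out = average_frame_input(frames, input_scale=1.0)
        np.testing.assert_allclose(out, frames.mean(axis=0))
        # columns are 0,3,...,42 etc. -> means 21, 22, 23
        np.testing.assert_allclose(out, [21.0, 22.0, 23.0])

    def test_input_scale_applied(self):
        frames = np.ones((4, 2))
        np.testing.assert_allclose(average_frame_input(frames, 10.0),
                                   [10.0, 10.0])

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError):
            average_frame_input(np.empty((0, 3)), 1.0)


class TestResponse:
    def test_identity_like_weights_copy_inputs(self):
        A = np.zeros((3, 2))
        A[0, 0] = 1.0
        A[2, 1] = 1.0
        conn = toy_connectome(A, [0.0, 0.0])
        r = complex_response(np.array([5.0, 7.0, 9.0]), conn)
        np.testing.assert_array_equal(r, [5.0, 9.0])

    def test_dot_product_by_hand(self):
        conn = toy_connectome([[0.5], [0.25]], [0.0])
        assert complex_response(np.array([1.0, 2.0]), conn)[0] == 1.0

    def test_zero_weights_zero_response(self):
        conn = toy_connectome(np.zeros((4, 3)), np.zeros(3))
        assert not np.any(complex_response(np.ones(4), conn))

    def test_shape_mismatch(self):
        conn = toy_connectome(np.zeros((4, 3)), np.zeros(3))
        with pytest.raises(ValueError):
            complex_response(np.ones(5), conn)


class TestNormalization:
    def test_zero_rates_stay_zero(self):
        np.testing.assert_array_equal(
            normalize_responses(np.zeros(5)), np.zeros(5))

    def test_scalar_arithmetic_oracle(self):
        """rates (3,4), alpha 0.01, beta 12: denominator 25.01."""
        out = normalize_responses(np.array([3.0, 4.0]), 0.01, 12.0)
        np.testing.assert_allclose(out, [36.0 / 25.01, 48.0 / 25.01])
        np.testing.assert_allclose(out, [1.43942423, 1.91923231], atol=1e-8)

    def test_ratios_preserved(self, rng):
        r = rng.uniform(0.1, 5.0, size=6)
        rn = normalize_responses(r)
        np.testing.assert_allclose(rn / rn[0], r / r[0])

    def test_alpha_guard(self):
        with pytest.raises(ValueError):
            normalize_responses(np.ones(3), alpha=0.0)


class TestBCMUpdate:
    def test_response_at_threshold_gives_pure_decay(self):
        """r == theta sits on the BCM zero crossing: the Hebbian term
        vanishes and only the decay -eta_a*gamma_a*a remains."""
        A = np.full((2, 1), 0.5)
        conn = toy_connectome(A, [2.0], eta_a=1e-3, gamma_a=1e-4)
        out = update_bcm(np.array([1.0, 1.0]), np.array([2.0]), conn)
        np.testing.assert_allclose(
            out.A_SC, A - conn.eta_a * conn.gamma_a * A)

    def test_hand_arithmetic_potentiation(self):
        """x=1, r=2, theta=1, a=0: da = 1e-3 * (1*2*(2-1)) = 2e-3."""
        conn = toy_connectome([[0.0]], [1.0], eta_a=1e-3, gamma_a=1e-4)
        out = update_bcm(np.array([1.0]), np.array([2.0]), conn)
        assert out.A_SC[0, 0] == pytest.approx(2e-3)

    def test_threshold_converges_geometrically_to_r_squared(self):
        """Clamped rates: |theta_t - r^2| shrinks by (1 - eta_theta) per
        step (closed form of the linear recursion)."""
        conn = toy_connectome(np.zeros((1, 1)), [5.0], eta_theta=1e-3)
        r = np.array([1.5])
        x = np.zeros(1)
        diffs = []
        for _ in range(50):
            diffs.append(abs(conn.theta[0] - 2.25))
            conn = update_bcm(x, r, conn)
        diffs = np.array(diffs)
        ratios = diffs[1:] / diffs[:-1]
        np.testing.assert_allclose(ratios, 1 - 1e-3, atol=1e-9)

    def test_weights_clipped_to_box(self):
        conn = toy_connectome([[0.999]], [0.0], eta_a=1.0, a2_max=1.0)
        out = update_bcm(np.array([5.0]), np.array([5.0]), conn)
        assert out.A_SC[0, 0] == 1.0

    def test_shape_mismatch(self):
        conn = toy_connectome(np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            update_bcm(np.ones(3), np.ones(2), conn)


class TestNBCMUpdate:
    def test_zero_rates_pure_decay(self):
        A = np.full((3, 2), 0.4)
        conn = toy_connectome(A, [0.5, 0.5], eta_a=1e-3, gamma_a=1e-4,
                              eta_theta=1e-3)
        out = update_nbcm(np.ones(3), np.zeros(2), conn)
        np.testing.assert_allclose(out.A_SC, A * (1 - 1e-3 * 1e-4))
        np.testing.assert_allclose(out.theta, 0.5 * (1 - 1e-3))

    def test_single_cell_scalar_oracle(self):
        """r=1, alpha=0.01, beta=12: r_N = 12/1.01; with theta=0, a=0,
        x=1, gamma ignored at a=0: da = 1e-3 * r_N^2 = 0.14116263..."""
        conn = toy_connectome([[0.0]], [0.0], eta_a=1e-3, gamma_a=1e-4,
                              alpha=0.01, beta=12.0)
        out = update_nbcm(np.array([1.0]), np.array([1.0]), conn)
        r_n = 12.0 / 1.01
        assert out.A_SC[0, 0] == pytest.approx(1e-3 * r_n ** 2, rel=1e-9)
        assert out.A_SC[0, 0] == pytest.approx(0.14116263, abs=1e-7)

    def test_only_active_cells_move_beyond_decay(self):
        A = np.full((2, 2), 0.2)
        conn = toy_connectome(A, [0.0, 0.0], gamma_a=0.0)
        out = update_nbcm(np.array([1.0, 1.0]), np.array([2.0, 0.0]), conn)
        assert np.all(out.A_SC[:, 0] > 0.2)       # active column moved
        np.testing.assert_array_equal(out.A_SC[:, 1], A[:, 1])

    def test_reduces_to_bcm_when_normalization_is_identity(self, rng):
        """Choosing beta = alpha + sum(r^2) makes r_N == r, and the NBCM
        update must then equal the BCM update exactly."""
        x = rng.uniform(0, 2, size=4)
        r = rng.uniform(0.1, 1.5, size=3)
        beta = 0.01 + float(np.sum(r ** 2))
        A = rng.uniform(0, 0.5, size=(4, 3))
        conn_n = toy_connectome(A.copy(), [0.3, 0.4, 0.5], alpha=0.01,
                                beta=beta)
        conn_b = toy_connectome(A.copy(), [0.3, 0.4, 0.5])
        out_n = update_nbcm(x, r, conn_n)
        out_b = update_bcm(x, r, conn_b)
        np.testing.assert_allclose(out_n.A_SC, out_b.A_SC, atol=1e-12)
        np.testing.assert_allclose(out_n.theta, out_b.theta, atol=1e-12)

    def test_bounds_invariant_under_fuzz(self, rng):
        conn = init_complex_connectome(5, 4, seed=rng, a_init=0.5,
                                       theta0=0.2)
        for _ in range(1000):
            x = np.abs(rng.standard_normal(5)) * rng.uniform(0, 3)
            r = complex_response(x, conn)
            update = update_nbcm if rng.random() < 0.5 else update_bcm
            conn = update(x, r, conn)
            assert np.all(conn.A_SC >= 0) and np.all(conn.A_SC <= 1.0)
            assert np.all(conn.theta >= 0)


class TestTraining:
    def test_zero_epochs_returns_seeded_initial(self, desk_simple_layer):
        cfg = ComplexTrainConfig(n_complex=4, epochs=0, a_init=0.1,
                                 theta0=1.0)
        conn, log = cl.train_complex_layer(desk_simple_layer, [], "bcm",
                                           cfg, seed=5)
        expected = init_complex_connectome(
            desk_simple_layer.n_simple, 4,
            seed=np.random.default_rng(5), a_init=0.1, theta0=1.0)
        np.testing.assert_array_equal(conn.A_SC, expected.A_SC)
        assert log.empty

    def test_unknown_rule_rejected(self, desk_simple_layer):
        with pytest.raises(ValueError, match="rule"):
            cl.train_complex_layer(desk_simple_layer, [], "oja",
                                   ComplexTrainConfig(), seed=0)

    def test_short_run_keeps_invariants(self, desk_simple_layer,
                                        desk_sequences, desk_config):
        cfg = desk_config.complex_train_config()
        cfg = replace(cfg, epochs=500, log_every=250)
        conn, log = cl.train_complex_layer(
            desk_simple_layer, desk_sequences[:50], "nbcm", cfg, seed=1)
        assert np.all(conn.A_SC >= 0) and np.all(conn.A_SC <= 1)
        assert len(log) == 2


class TestEvokedInputs:
    def test_spontaneous_subtraction_zeroes_blank_sequences(
            self, desk_simple_layer, desk_config):
        from v1complex.stimuli import FrameSequence

        M = desk_simple_layer.M
        blank = FrameSequence(np.zeros((3, M, M)))
        x = cl.compute_complex_inputs(desk_simple_layer, [blank],
                                      desk_config.layer_constants(),
                                      input_scale=1.0, evoked=True)
        np.testing.assert_allclose(x, 0.0, atol=1e-12)

    def test_absolute_includes_spontaneous(self, desk_simple_layer,
                                           desk_config):
        from v1complex.stimuli import FrameSequence

        M = desk_simple_layer.M
        blank = FrameSequence(np.zeros((2, M, M)))
        x = cl.compute_complex_inputs(desk_simple_layer, [blank],
                                      desk_config.layer_constants(),
                                      input_scale=1.0, evoked=False)
        spont = cl.simple_spontaneous_rates(desk_simple_layer,
                                            desk_config.layer_constants())
        np.testing.assert_allclose(x[0], spont, atol=1e-12)


class TestPoolingSummaries:
    def test_substantial_patterns_counts_distinct_columns(self):
        A = np.array([[0.9, 0.9, 0.0],
                      [0.0, 0.0, 0.9],
                      [0.5, 0.5, 0.0]])
        assert substantial_patterns(A) == 2
        assert recruited_simple_cells(A) == 3

    def test_empty_columns_share_one_pattern(self):
        A = np.zeros((4, 3))
        assert substantial_patterns(A) == 1
        assert recruited_simple_cells(A) == 0

    def test_mean_pairwise_cosine(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert mean_pairwise_cosine(A) == pytest.approx(0.0)
        B = np.array([[1.0, 2.0], [0.0, 0.0]])
        assert mean_pairwise_cosine(B) == pytest.approx(1.0)
        assert np.isnan(mean_pairwise_cosine(np.zeros((3, 2))))


def test_complex_connectome_hdf5_roundtrip(tmp_path, rng):
    conn = init_complex_connectome(6, 4, seed=rng, a_init=0.2, theta0=0.7,
                                   beta=11.0)
    path = tmp_path / "cc.h5"
    cl.save_complex_connectome(path, conn)
    loaded = cl.load_complex_connectome(path)
    np.testing.assert_array_equal(loaded.A_SC, conn.A_SC)
    np.testing.assert_array_equal(loaded.theta, conn.theta)
    assert loaded.beta == 11.0
    assert loaded.n_frames == conn.n_frames
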