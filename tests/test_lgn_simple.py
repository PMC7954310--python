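"""LGN/simple-cell dynamics and Hebbian/anti-Hebbian plasticity."""

from dataclasses import replace

import numpy as np
import pytest

from v1complex import lgn_simple as ls
from v1complex.lgn_simple import (DynamicsDivergenceError, LayerConstants,
                                  SimpleConnectome, init_simple_connectome,
                                  run_dynamics, synaptic_field,
                                  update_weights_simple)


def tiny_connectome(M=1, n_simple=1, fill=0.0, a1_max=0.3):
    shape = (2 * M * M, n_simple)
    z = np.full(shape, fill)
    return SimpleConnectome(
        A_u_plus=np.clip(z, 0, a1_max), A_u_minus=np.clip(-z, -a1_max, 0),
        A_d_plus=np.clip(z, 0, a1_max), A_d_minus=np.clip(-z, -a1_max, 0),
        a1_max=a1_max)


class TestDynamics:
    def test_lgn_spontaneous_fixed_point(self):
        """Zero stimulus and zero weights: every LGN cell settles at the
        spontaneous rate of 0.5 Hz."""
        conn = tiny_connectome(M=3, n_simple=4)
        state = run_dynamics(np.zeros(9), np.zeros(9), conn,
                             LayerConstants())
        np.testing.assert_allclose(state.r_L, 0.5, atol=1e-3)

    def test_simple_cells_silent_below_threshold(self):
        """With no LGN drive and leak below the rectifier threshold,
        simple cells never fire."""
        conn = tiny_connectome(M=2, n_simple=3)
        consts = LayerConstants(v_leak_S=0.05, lambda_S=0.1)
        state = run_dynamics(np.zeros(4), np.zeros(4), conn, consts)
        assert not np.any(state.r_S)

    def test_matches_scalar_recursion(self):
        """Full trajectory on a 2-LGN/1-simple system equals an
        independent step-by-step scalar recursion to 1e-12."""
        consts = LayerConstants()
        au_p, au_m = 0.25, -0.1
        ad_p, ad_m = 0.1, -0.25
        conn = SimpleConnectome(
            A_u_plus=np.array([[au_p], [au_p / 2]]),
            A_u_minus=np.array([[au_m], [au_m / 2]]),
            A_d_plus=np.array([[ad_p], [ad_p / 2]]),
            A_d_minus=np.array([[ad_m], [ad_m / 2]]))
        x_on, x_off = np.array([0.8]), np.array([0.3])

        # scalar recursion (staggered update: LGN step, refreshed LGN
        # rates feed the simple-cell step)
        kL = consts.dt / consts.tau_L
        kS = consts.dt / consts.tau_S
        vL = [0.0, 0.0]
        vS = 0.0
        rL = [0.0, 0.0]
        rS = 0.0
        x = [0.8, 0.3]
        for _ in range(consts.n_steps):
            for i, scale in enumerate([1.0, 0.5]):
                fb = (ad_p + ad_m) * scale * rS
                vL[i] = vL[i] + kL * (-vL[i] + x[i] + fb + consts.r_b_L)
                rL[i] = max(vL[i], 0.0)
            drive = ((au_p + au_m) * rL[0]
                     + (au_p + au_m) * 0.5 * rL[1])
            vS = vS + kS * (-(vS - consts.v_leak_S) + drive + rS)
            rS = max(vS - consts.lambda_S, 0.0)

        state = run_dynamics(x_on, x_off, conn, consts)
        np.testing.assert_allclose(state.v_L, vL, atol=1e-12)
        np.testing.assert_allclose(state.v_S, [vS], atol=1e-12)
        np.testing.assert_allclose(state.r_S, [rS], atol=1e-12)

    def test_rates_nonnegative_and_consistent(self, rng):
        conn = init_simple_connectome(4, 6, seed=rng)
        x = np.abs(rng.standard_normal((16, 8))) * 0.3
        state = run_dynamics(x, 0 * x, conn, LayerConstants())
        assert np.all(state.r_L >= 0) and np.all(state.r_S >= 0)
        np.testing.assert_allclose(state.r_L, np.maximum(state.v_L, 0))
        np.testing.assert_allclose(
            state.r_S, np.maximum(state.v_S - 0.1, 0))

    def test_divergence_guard_names_step(self):
        # a strong positive self-loop through huge mutually excitatory
        # weights drives the potentials past the guard
        M = 2
        big = np.full((2 * M * M, 2), 0.3)
        conn = SimpleConnectome(A_u_plus=big * 1e3, A_u_minus=0 * big,
                                A_d_plus=big * 1e3, A_d_minus=0 * big,
                                a1_max=1e3)
        with pytest.raises(DynamicsDivergenceError, match="step"):
            run_dynamics(np.ones(4), np.ones(4), conn, LayerConstants())

    def test_shape_mismatch_rejected(self):
        conn = tiny_connectome(M=2)
        with pytest.raises(ValueError):
            run_dynamics(np.zeros(5), np.zeros(5), conn)


class TestPlasticity:
    def test_hand_computed_outer_product(self):
        """2 LGN x 1 simple cell, one presentation: the Hebbian term is
        eta1 * (r_L - r_b) outer r_S, here ((1.0)*2, (0.0)*2)."""
        conn = tiny_connectome(M=1, n_simple=1)  # all-zero weights
        conn = replace(conn, eta1=3.0, gamma1=1e-3)
        r_L = np.array([[1.5], [0.5]])
        r_S = np.array([[2.0]])
        out = update_weights_simple(r_L, r_S, conn, LayerConstants())
        # Delta = eta*(H - gamma*0), H = [[1.0*2], [0.0*2]], clipped to 0.3
        np.testing.assert_allclose(out.A_u_plus, [[0.3], [0.0]])
        np.testing.assert_allclose(out.A_u_minus, [[0.0], [0.0]])
        # anti-Hebbian feedback moves opposite
        np.testing.assert_allclose(out.A_d_minus, [[-0.3], [0.0]])
        np.testing.assert_allclose(out.A_d_plus, [[0.0], [0.0]])

    def test_zero_simple_rates_pure_decay(self):
        """Silent simple cells leave only the weight-decay term, which
        shrinks every matrix toward zero by a factor eta1*gamma1."""
        M, n = 2, 3
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 0.3, size=(8, n))
        conn = SimpleConnectome(A_u_plus=w, A_u_minus=-w, A_d_plus=w,
                                A_d_minus=-w, eta1=3.0, gamma1=1e-3)
        r_L = np.full((8, 5), 0.5)  # at baseline: Hebbian term zero anyway
        r_S = np.zeros((n, 5))
        out = update_weights_simple(r_L, r_S, conn)
        np.testing.assert_allclose(out.A_u_plus, w * (1 - 3e-3))
        np.testing.assert_allclose(out.A_d_minus, -w * (1 - 3e-3))

    def test_weight_at_bound_stays_at_bound(self):
        conn = tiny_connectome(M=1, n_simple=1, fill=0.3)
        r_L = np.array([[2.0], [2.0]])  # strong positive Hebbian drive
        r_S = np.array([[1.0]])
        out = update_weights_simple(r_L, r_S, conn)
        assert out.A_u_plus.max() == pytest.approx(0.3)

    def test_centered_update_equals_covariance(self, rng):
        conn = init_simple_connectome(2, 3, seed=rng)
        r_L = rng.uniform(0, 2, size=(8, 10))
        r_S = rng.uniform(0, 1, size=(3, 10))
        out = update_weights_simple(r_L, r_S, conn, center=True)
        H = np.cov(np.vstack([r_L, r_S]), bias=True)[:8, 8:]
        expected = np.clip(conn.A_u_plus + 3.0 * (H - 1e-3 * conn.A_u_plus),
                           0, 0.3)
        np.testing.assert_allclose(out.A_u_plus, expected, atol=1e-12)

    def test_sign_and_bound_invariants_under_fuzz(self, rng):
        """Randomized rate batches never push any matrix out of its
        sign/magnitude box."""
        conn = init_simple_connectome(2, 4, seed=rng)
        for _ in range(300):
            r_L = np.abs(rng.standard_normal((8, 7))) * rng.uniform(0, 4)
            r_S = np.abs(rng.standard_normal((4, 7))) * rng.uniform(0, 4)
            conn = update_weights_simple(r_L, r_S, conn,
                                         center=rng.random() < 0.5)
            assert conn.check_bounds()

    def test_shape_mismatch_rejected(self, rng):
        conn = init_simple_connectome(2, 3, seed=rng)
        with pytest.raises(ValueError):
            update_weights_simple(np.zeros((8, 5)), np.zeros((3, 4)), conn)


class TestInitialization:
    def test_mirror_constraint_at_init(self, rng):
        conn = init_simple_connectome(4, 8, seed=rng)
        np.testing.assert_array_equal(conn.A_d_minus, -conn.A_u_plus)
        np.testing.assert_array_equal(conn.A_d_plus, -conn.A_u_minus)
        assert conn.check_bounds()

    def test_columns_zero_sum_unit_norm(self, rng):
        # at realistic geometry (288 LGN cells) no entry reaches the
        # clipping bound, so the balanced unit-norm construction is exact
        conn = init_simple_connectome(12, 8, seed=rng)
        net = conn.A_u_plus + conn.A_u_minus
        np.testing.assert_allclose(net.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(net, axis=0), 1.0,
                                   atol=1e-9)

    def test_seeded_reproducible(self):
        a = init_simple_connectome(3, 5, seed=11)
        b = init_simple_connectome(3, 5, seed=11)
        np.testing.assert_array_equal(a.A_u_plus, b.A_u_plus)


class TestTraining:
    def test_zero_epochs_returns_initial_connectome(self, rng):
        imgs = [rng.uniform(0, 1, size=(32, 32))]
        cfg = ls.SimpleTrainConfig(M=8, n_simple=4, epochs=0)
        conn, log = ls.train_simple_layer(imgs, cfg, seed=42)
        expected = init_simple_connectome(8, 4, seed=np.random.default_rng(42))
        np.testing.assert_array_equal(conn.A_u_plus, expected.A_u_plus)
        assert log.empty

    def test_short_training_keeps_invariants(self, rng):
        imgs = [rng.uniform(0, 1, size=(40, 40)) for _ in range(2)]
        cfg = ls.SimpleTrainConfig(M=8, n_simple=5, epochs=20,
                                   batch_size=20, log_every=10)
        conn, log = ls.train_simple_layer(imgs, cfg, seed=3)
        assert conn.check_bounds()
        assert list(log["epoch"]) == [10, 20]


class TestSynapticField:
    def test_zero_weights_zero_field(self):
        conn = tiny_connectome(M=3, n_simple=2)
        assert not np.any(synaptic_field(conn, 0))

    def test_single_on_weight(self):
        M = 3
        conn = tiny_connectome(M=M, n_simple=1)
        A = conn.A_u_plus.copy()
        A[4, 0] = 0.3               # ON pixel (1,1)
        conn = replace(conn, A_u_plus=A)
        field = synaptic_field(conn, 0)
        assert field[1, 1] == pytest.approx(0.3)
        assert np.count_nonzero(field) == 1

    def test_off_excitation_and_on_inhibition_sum_negative(self):
        M = 2
        conn = tiny_connectome(M=M, n_simple=1)
        Ap = conn.A_u_plus.copy()
        Am = conn.A_u_minus.copy()
        Ap[4 + 3, 0] = 0.2          # OFF channel, pixel (1,1)
        Am[3, 0] = -0.1             # ON channel, same pixel
        conn = replace(conn, A_u_plus=Ap, A_u_minus=Am)
        field = synaptic_field(conn, 0)
        assert field[1, 1] == pytest.approx(-0.3)

    def test_index_out_of_range(self):
        conn = tiny_connectome(M=2, n_simple=2)
        with pytest.raises(IndexError):
            synaptic_field(conn, 2)


def test_connectome_hdf5_roundtrip(tmp_path, rng):
    conn = init_simple_connectome(3, 4, seed=rng)
    consts = LayerConstants(v_leak_S=0.02)
    path = tmp_path / "conn.h5"
    ls.save_connectome(path, conn, consts)
    loaded, loaded_consts = ls.load_connectome(path)
    np.testing.assert_array_equal(loaded.A_u_plus, conn.A_u_plus)
    np.testing.assert_array_equal(loaded.A_d_minus, conn.A_d_minus)
    assert loaded_consts.v_leak_S == pytest.approx(0.02)
    assert loaded_consts.n_steps == consts.n_steps
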