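"""Motor cortex: afferent integration, coupling, lesions, readout training."""

import numpy as np
import pytest

from cbgreach.motor_cortex import (LesionSpec, MCInputGains, ReadoutWeights,
                                   apply_lesion, coupled_mc_input, delta_rule_update,
                                   lesion_mask, mc_input, mn_readout, train_mc_mn)


class TestAfferentSum:
    def test_zero_gains_give_zero_sheet(self, rng):
        sheets = [rng.random((5, 5)) for _ in range(3)]
        out = mc_input(*sheets, MCInputGains(0, 0, 0))
        assert np.all(out == 0)

    def test_single_gain_passes_through(self, rng):
        s = rng.random((5, 5))
        out = mc_input(s, np.zeros((5, 5)), np.zeros((5, 5)), MCInputGains(1, 0, 0))
        assert np.array_equal(out, s)

    def test_matches_elementwise_oracle(self, rng):
        a, b, c = (rng.random((4, 4)) for _ in range(3))
        out = mc_input(a, b, c, MCInputGains(0.5, 1.5, 2.0))
        assert np.allclose(out, 0.5 * a + 1.5 * b + 2.0 * c, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mc_input(rng.random((4, 4)), rng.random((5, 5)), rng.random((4, 4)),
                     MCInputGains())

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            MCInputGains(A_PC=-0.1)


class TestCoupling:
    def test_zero_coupling_reduces_to_plain_sum(self, rng):
        sheets = [rng.random((5, 5)) for _ in range(3)]
        other = rng.random((5, 5))
        g = MCInputGains(0.3, 0.7, 1.1)
        assert np.allclose(coupled_mc_input(*sheets, g, 0.0, other),
                           mc_input(*sheets, g))

    def test_inhibitory_coupling_subtracts_scaled_sheet(self, rng):
        sheets = [rng.random((5, 5)) for _ in range(3)]
        g = MCInputGains(1, 1, 1)
        ones = np.ones((5, 5))
        assert np.allclose(coupled_mc_input(*sheets, g, -0.5, ones),
                           mc_input(*sheets, g) - 0.5)

    def test_coupling_is_linear_in_epsilon(self, rng):
        sheets = [rng.random((5, 5)) for _ in range(3)]
        other = rng.random((5, 5))
        g = MCInputGains(0.2, 0.4, 0.6)
        lhs = (coupled_mc_input(*sheets, g, 0.3, other)
               + coupled_mc_input(*sheets, g, -0.8, other)
               - mc_input(*sheets, g))
        rhs = coupled_mc_input(*sheets, g, 0.3 - 0.8, other)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestLesion:
    def test_suppression_factor_applied(self):
        g = np.ones((15, 15))
        out = apply_lesion(g, LesionSpec(size=1, centre=(7, 7)))
        assert out[7, 7] == pytest.approx(0.01)
        assert out.sum() == pytest.approx(15 * 15 - 1 + 0.01)

    def test_single_node_lesion_suppresses_exactly_one(self):
        mask = lesion_mask(LesionSpec(size=1, centre=(3, 4)), 15)
        assert mask.sum() == 1 and mask[3, 4]

    def test_counting_oracle_7x7(self, rng):
        g = rng.random((15, 15))
        lesion = LesionSpec(size=7, centre=(8, 8))
        mask = lesion_mask(lesion, 15)
        assert mask.sum() == 49
        out = apply_lesion(g, lesion)
        assert out[mask].sum() == pytest.approx(0.01 * g[mask].sum())
        assert np.array_equal(out[~mask], g[~mask])

    def test_edge_lesion_is_clipped(self):
        mask = lesion_mask(LesionSpec(size=5, centre=(0, 0)), 15)
        assert mask.sum() == 9  # 3x3 survives clipping at the corner

    def test_zero_size_lesion_is_noop(self, rng):
        g = rng.random((6, 6))
        assert np.array_equal(apply_lesion(g, LesionSpec(size=0, centre=(2, 2))), g)
        assert np.array_equal(apply_lesion(g, None), g)


class TestReadout:
    def test_zero_sheet_gives_zero_activation(self):
        w = ReadoutWeights.zeros(5)
        assert np.all(mn_readout(np.zeros((5, 5)), w) == 0)

    def test_selector_weights_pick_nodes(self, rng):
        G = rng.random((4, 4))
        W = np.zeros((4, 16))
        picks = [0, 5, 10, 15]
        for r, p in enumerate(picks):
            W[r, p] = 1.0
        w = ReadoutWeights(W=W, A_MN=1.0)
        assert np.allclose(mn_readout(G, w, clip=False), G.ravel()[picks])

    def test_matches_matrix_vector_oracle(self, rng):
        G = rng.random((5, 5))
        W = rng.normal(size=(4, 25))
        w = ReadoutWeights(W=W, A_MN=1.3)
        assert np.allclose(mn_readout(G, w, clip=False), 1.3 * W @ G.ravel(),
                           atol=1e-12)

    def test_clipping_to_unit_interval(self, rng):
        W = 100 * rng.normal(size=(4, 25))
        phi = mn_readout(rng.random((5, 5)), ReadoutWeights(W=W))
        assert np.all(phi >= 0) and np.all(phi <= 1)


class TestDeltaRule:
    def test_no_error_no_update(self, rng):
        w = ReadoutWeights(W=rng.normal(size=(4, 25)))
        before = w.W.copy()
        phi = rng.random(4)
        delta_rule_update(w, phi, phi, rng.random((5, 5)))
        assert np.array_equal(w.W, before)

    def test_weights_unchanged_where_sheet_is_zero(self, rng):
        w = ReadoutWeights.zeros(5)
        G = rng.random((5, 5))
        G[2, :] = 0.0
        delta_rule_update(w, rng.random(4), rng.random(4), G)
        cols = np.flatnonzero(G.ravel() == 0)
        assert np.all(w.W[:, cols] == 0)

    def test_training_error_decreases_on_fixed_sample(self, rng):
        # linear loop: phi = W @ vec(G) for a fixed sheet
        G = rng.random((5, 5))
        phi_d = np.array([[0.4, 0.6, 0.2, 0.8]])

        def loop(pd, w):
            return G, w.A_MN * (w.W @ G.ravel())

        w0 = ReadoutWeights.zeros(5, eta=0.05)
        _, hist = train_mc_mn(loop, phi_d, w0, sweeps=6, tol=1e-9)
        assert all(b < a for a, b in zip(hist, hist[1:]))

    def test_training_is_reproducible(self, rng):
        G = rng.random((5, 5))
        phi_d = rng.random((10, 4))

        def loop(pd, w):
            return G, w.A_MN * (w.W @ G.ravel())

        w1, _ = train_mc_mn(loop, phi_d, ReadoutWeights.zeros(5), sweeps=3)
        w2, _ = train_mc_mn(loop, phi_d, ReadoutWeights.zeros(5), sweeps=3)
        assert np.array_equal(w1.W, w2.W)

    def test_divergence_aborts_with_diagnostic(self, rng):
        G = 10 * np.ones((5, 5))

        def loop(pd, w):  # eta far too large for this sheet: error grows
            return G, w.A_MN * (w.W @ G.ravel())

        w = ReadoutWeights.zeros(5, eta=0.5)
        with pytest.raises(RuntimeError, match="diverged"):
            train_mc_mn(loop, np.tile([1, 1, 1, 1.0], (4, 1)), w, sweeps=10)
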