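"""Basal ganglia: value function, MSN gating, STN-GPe dynamics, GPi."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbgreach.basal_ganglia import (MSNParams, STNGPeParams, STNGPeState, ValueParams,
                                    gpi_integrate, msn_gate, stn_gpe_lateral_kernel,
                                    stn_gpe_step, value_difference, value_function)


class TestValue:
    def test_value_is_one_at_target(self, rng):
        x = rng.normal(size=2)
        assert value_function(x, x, ValueParams(0.2)) == pytest.approx(1.0)

    def test_value_at_one_sigma(self):
        p = ValueParams(sigma_V=0.25)
        assert value_function([0, 0], [0.25, 0], p) == pytest.approx(np.exp(-1))

    def test_matches_substitution_oracle(self, rng):
        p = ValueParams(sigma_V=0.13)
        for _ in range(30):
            a, b = rng.normal(size=2), rng.normal(size=2)
            expected = np.exp(-np.sum((b - a) ** 2) / 0.13 ** 2)
            assert value_function(a, b, p) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.05, 0.5), st.floats(0.01, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_wider_sigma_raises_value_at_fixed_distance(self, sigma, dist):
        v1 = value_function([0, 0], [dist, 0], ValueParams(sigma))
        v2 = value_function([0, 0], [dist, 0], ValueParams(2 * sigma))
        assert v2 > v1

    def test_difference_signal(self):
        assert value_difference(0.8, 0.8) == 0.0
        assert value_difference(0.9, 0.5) > 0  # improvement: direct pathway
        assert value_difference(0.2, 0.5) < 0  # worsening: indirect pathway

    def test_non_finite_positions_rejected(self):
        with pytest.raises(ValueError):
            value_function([np.nan, 0], [0, 0], ValueParams())


class TestMSNGate:
    def gates(self, dv, p=MSNParams()):
        ones = np.ones((1, 1))
        y1, y2 = msn_gate(dv, ones, p)
        return float(y1[0, 0]), float(y2[0, 0])

    def test_direct_gate_half_at_threshold(self):
        g1, _ = self.gates(0.0)  # t_D1 = 0
        assert g1 == pytest.approx(0.5, abs=1e-12)

    def test_table_parameter_substitution(self):
        # lambda = +-50, t_D1 = 0, t_D2 = 0.05 at delta_V = 0.1
        g1, g2 = self.gates(0.1)
        assert g1 == pytest.approx(1 / (1 + np.exp(-5)), abs=1e-9)
        assert g2 == pytest.approx(1 / (1 + np.exp(50 * 0.05)), abs=1e-9)

    def test_extreme_improvement_switches_pathways(self):
        g1, g2 = self.gates(1.0)
        assert g1 > 0.999 and g2 < 1e-6

    def test_gates_scale_sheet_elementwise(self, rng):
        dG = rng.normal(size=(4, 4))
        y1, y2 = msn_gate(0.03, dG, MSNParams())
        g1 = 1 / (1 + np.exp(-50 * 0.03))
        g2 = 1 / (1 + np.exp(50 * (0.03 - 0.05)))
        assert np.allclose(y1, g1 * dG, atol=1e-12)
        assert np.allclose(y2, g2 * dG, atol=1e-12)

    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_pathway_complementarity_and_monotonicity(self, a, b):
        lo, hi = min(a, b), max(a, b)
        g1_lo, g2_lo = self.gates(lo)
        g1_hi, g2_hi = self.gates(hi)
        for g in (g1_lo, g2_lo, g1_hi, g2_hi):
            assert 0 < g < 1
        if hi - lo > 1e-9:
            assert g1_hi > g1_lo  # direct gate rises with delta_V
            assert g2_hi < g2_lo  # indirect gate falls

    def test_opposed_gains_enforced(self):
        with pytest.raises(ValueError):
            MSNParams(lambda_D1=50.0, lambda_D2=-40.0)


class TestSTNGPe:
    def test_zero_state_zero_input_is_fixed_point(self):
        st0 = STNGPeState(x_GPe=np.zeros((5, 5)), x_STN=np.zeros((5, 5)))
        st1 = stn_gpe_step(st0, np.zeros((5, 5)))
        assert np.all(st1.x_GPe == 0) and np.all(st1.x_STN == 0)

    def test_single_step_matches_loop_oracle(self, rng):
        n = 3
        p = STNGPeParams()
        st = STNGPeState.random(n, rng, params=p)
        y_d2 = rng.normal(size=(n, n))
        kg = stn_gpe_lateral_kernel(p.sigma_lat_g, n)
        ks = stn_gpe_lateral_kernel(p.sigma_lat_s, n)

        def corr(kern, sheet):
            out = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    for a in range(n):
                        for b in range(n):
                            out[i, j] += kern[i - a + n - 1, j - b + n - 1] * sheet[a, b]
            return out

        e_gpe = st.x_GPe + (p.dt / p.tau_GPe) * (
            -st.x_GPe + p.eps_g * corr(kg, st.x_GPe)
            + p.w_sg * st.y_STN + y_d2)
        e_stn = st.x_STN + (p.dt / p.tau_STN) * (
            -st.x_STN + p.eps_s * corr(ks, st.y_STN) - p.w_gs * st.x_GPe)
        nxt = stn_gpe_step(st, y_d2)
        assert np.allclose(nxt.x_GPe, e_gpe, atol=1e-10)
        assert np.allclose(nxt.x_STN, e_stn, atol=1e-10)
        assert np.allclose(nxt.y_STN, np.tanh(p.lambda_STN * e_stn), atol=1e-12)

    def test_stn_output_bounded_by_one(self, rng):
        st = STNGPeState.random(8, rng, amplitude=0.5)
        for _ in range(200):
            st = stn_gpe_step(st, np.zeros((8, 8)))
            assert np.abs(st.y_STN).max() <= 1.0

    def test_low_striatal_input_gives_decorrelated_oscillation(self, rng):
        # calibration: sustained, weakly correlated temporal activity
        st = STNGPeState.random(15, rng)
        traces = []
        for t in range(700):
            st = stn_gpe_step(st, np.zeros((15, 15)))
            if t >= 300:
                traces.append(st.y_STN.ravel().copy())
        traces = np.array(traces)
        sd = traces.std(axis=0)
        active = sd > 0.02
        assert active.sum() > 100  # most nodes keep oscillating
        c = np.corrcoef(traces[:, active].T)
        iu = np.triu_indices_from(c, 1)
        assert np.abs(c[iu]).mean() < 0.5

    def test_dt_stability_guard(self):
        with pytest.raises(ValueError):
            STNGPeParams(tau_STN=0.05, dt=0.1)


class TestGPi:
    def test_no_stn_gives_scaled_direct(self, rng):
        y1 = rng.normal(size=(4, 4))
        assert np.allclose(gpi_integrate(y1, np.zeros((4, 4)), A_D1=1.7),
                           1.7 * y1)

    def test_equal_sheets_cancel_at_unit_gains(self, rng):
        y = rng.normal(size=(4, 4))
        assert np.allclose(gpi_integrate(y, y, 1.0, 1.0), 0.0)

    def test_matches_elementwise_oracle(self, rng):
        y1, ys = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        assert np.allclose(gpi_integrate(y1, ys, 0.7, 1.9), 0.7 * y1 - 1.9 * ys,
                           atol=1e-12)

    def test_explore_gate_attenuates_stn_term(self, rng):
        y1, ys = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        out = gpi_integrate(y1, ys, 1.0, 2.0, explore_gate=0.25)
        assert np.allclose(out, y1 - 2.0 * 0.25 * ys, atol=1e-12)
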