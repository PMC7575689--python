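import numpy as np
import pytest

import engramnet.network as nw
from engramnet.connectivity import build_connectivity
from engramnet.network import (NetworkState, euler_step, init_state,
                               network_derivatives, plasticity_derivatives,
                               simulate_span, transfer_rate)
from engramnet.params import ModelParams


class TestTransfer:
    def test_midpoint_is_half_max(self):
        assert transfer_rate(130.0) == pytest.approx(50.0)

    def test_saturation_limits(self):
        assert transfer_rate(1e6) == pytest.approx(100.0)
        assert transfer_rate(-1e6) == pytest.approx(0.0, abs=1e-12)

    def test_rest_value(self):
        # alpha / (1 + e^{6.5})
        assert transfer_rate(0.0) == pytest.approx(100 / (1 + np.exp(6.5)),
                                                   rel=1e-12)

    def test_strictly_increasing_and_bounded(self):
        # strict monotonicity where double precision resolves the slope
        u = np.linspace(-200, 400, 2001)
        f = transfer_rate(u)
        assert np.all(np.diff(f) > 0)
        u_wide = np.linspace(-5000, 5000, 101)
        f_wide = transfer_rate(u_wide)
        assert np.all((f_wide >= 0) & (f_wide <= 100))
        assert np.all((f > 0) & (f < 100))


@pytest.fixture
def small_net(small_params):
    rng = np.random.default_rng(42)
    conn = build_connectivity(small_params, rng)
    state = init_state(small_params, conn, rng)
    return small_params, conn, state


class TestDerivatives:
    def test_zero_weights_give_pure_input_drive(self, small_net):
        p, conn, state = small_net
        state.u[:] = 0.0
        state.W_rec.data[:] = 0.0
        state.W_ff[:] = 0.0
        k = int(np.flatnonzero(conn.c_ff[0])[0])
        state.W_ff[0, k] = 2.0
        rates = np.zeros(p.nI)
        rates[k] = 130.0
        du, du_inh = network_derivatives(state, rates, p, conn)
        # at u=0 the leak vanishes but every neuron still fires at F(0),
        # driving the (weightless) network only through neuron 0's synapse
        # and the inhibitory feedback
        f_inh = transfer_rate(0.0)
        assert du[0] == pytest.approx(p.R * (2.0 * 130.0 - p.w_inh_out * f_inh))
        assert np.allclose(du[1:], -p.R * p.w_inh_out * f_inh)

    def test_isolated_neuron_steady_state(self):
        """A leaky integrator under constant drive D settles at u* = tau R D."""
        p = ModelParams(nM=1, grid_shape=(1, 1), nI=1, fanin=1, radius=0,
                        w_inh_out=0.0, w_inh_in=0.0)
        rng = np.random.default_rng(0)
        conn = build_connectivity(p, rng)
        state = init_state(p, conn, rng)
        state.W_ff[:] = 5.0
        D = 5.0 * 130.0
        simulate_span(state, np.array([130.0]), 1.0, p, conn, plastic=False)
        assert state.u[0] == pytest.approx(p.tau * p.R * D, rel=1e-6)

    def test_shape_mismatch_raises(self, small_net):
        p, conn, state = small_net
        with pytest.raises(ValueError):
            network_derivatives(state, np.zeros(5), p, conn)


class TestPlasticity:
    def test_scaling_term_vanishes_at_target_rate(self, small_net):
        p, conn, state = small_net
        # put every neuron exactly at the target rate
        u_t = float(np.asarray(p.epsilon)) - np.log(p.alpha / p.F_T - 1) / p.beta
        state.u[:] = u_t
        rates = np.full(p.nI, 7.0)
        dW_ff, dw_rec = plasticity_derivatives(state, rates, p, conn)
        expected_ff = p.mu * p.F_T * 7.0
        assert np.allclose(dW_ff[conn.c_ff], expected_ff)
        assert np.allclose(dw_rec, p.mu * p.F_T**2)

    def test_balance_weight_is_plasticity_fixed_point(self, small_net):
        """At saturation rates and w = w_hat_rec the Hebbian and scaling
        terms cancel."""
        p, conn, state = small_net
        state.u[:] = 1e4      # saturated: F = alpha to double precision
        state.W_rec.data[:] = p.derived().w_hat_rec
        _, dw_rec = plasticity_derivatives(state, np.zeros(p.nI), p, conn)
        assert np.max(np.abs(dw_rec)) < 1e-6

    def test_heterosynaptic_depression_sign(self, small_net):
        """Active postsynaptic neuron + silent input => feed-forward weight
        decreases (depression by scaling)."""
        p, conn, state = small_net
        state.u[:] = 1e4
        dW_ff, _ = plasticity_derivatives(state, np.zeros(p.nI), p, conn)
        assert np.all(dW_ff[conn.c_ff & (state.W_ff > 0)] < 0)

    def test_single_synapse_scaling_fixed_point_reached(self):
        """A clamped synapse converges to the closed-form balance weight
        within 1%, for both synapse classes."""
        p = ModelParams()
        for kappa, f_pre, expected in [(p.kappa_rec, p.alpha, 77.4984),
                                       (p.kappa_ff, 130.0, 306.0943)]:
            w = 10.0
            for _ in range(int(60.0 / p.dt)):
                w += p.dt * p.mu * (p.alpha * f_pre
                                    + (p.F_T - p.alpha) * w * w / kappa)
            assert w == pytest.approx(expected, rel=0.01)

    def test_weights_cannot_cross_zero_without_clamping(self):
        """The depression term is proportional to w^2, so a finely resolved
        single synapse decays toward zero but never crosses it."""
        p = ModelParams()
        w = 5.0
        dt = 1e-5
        for _ in range(200_000):
            w += dt * p.mu * (p.F_T - p.alpha) * w * w / p.kappa_rec
        assert 0.0 < w < 5.0


class TestEulerStep:
    def test_plasticity_off_conserves_weights_bitwise(self, small_net):
        p, conn, state = small_net
        before_rec = state.W_rec.data.copy()
        before_ff = state.W_ff.copy()
        rates = np.full(p.nI, 130.0)
        simulate_span(state, rates, 0.5, p, conn, plastic=False)
        assert np.array_equal(state.W_rec.data, before_rec)
        assert np.array_equal(state.W_ff, before_ff)

    def test_zero_state_zero_input_drifts_only_through_baseline_rate(self, small_net):
        p, conn, state = small_net
        state.u[:] = 0.0
        state.W_rec.data[:] = 0.0
        state.W_ff[:] = 0.0
        out = euler_step(state, np.zeros(p.nI), p, conn, plastic=False)
        # baseline firing F(0) ~ 0.15 Hz still feeds the inhibitory unit
        assert np.allclose(out.u, -p.dt * p.R * p.w_inh_out * transfer_rate(0.0))

    def test_euler_convergence_order(self, small_params):
        """Halving dt roughly halves the endpoint error against a fine-dt
        reference (explicit Euler is first order)."""
        rng = np.random.default_rng(7)
        conn = build_connectivity(small_params, rng)
        rates = np.zeros(small_params.nI)
        rates[:4] = 130.0

        def endpoint(dt):
            p = small_params.replace(dt=dt)
            st = init_state(p, conn, np.random.default_rng(7))
            simulate_span(st, rates, 0.5, p, conn, plastic=True)
            return st.u.copy()

        ref = endpoint(0.0005)
        err_coarse = np.max(np.abs(endpoint(0.004) - ref))
        err_fine = np.max(np.abs(endpoint(0.002) - ref))
        assert err_fine < err_coarse
        assert err_coarse / err_fine == pytest.approx(2.0, rel=0.7)

    def test_kernel_matches_reference_path(self, small_net):
        """The compiled span kernel and the pure-numpy step agree to
        rounding over hundreds of plastic steps."""
        if nw._fast_span is None:
            pytest.skip("compiled kernel unavailable")
        p, conn, state = small_net
        rates = np.zeros(p.nI)
        rates[:6] = 130.0
        st_fast = state.copy()
        st_ref = state.copy()
        simulate_span(st_fast, rates, 1.0, p, conn, plastic=True)
        old = nw._fast_span
        nw._fast_span = None
        try:
            simulate_span(st_ref, rates, 1.0, p, conn, plastic=True)
        finally:
            nw._fast_span = old
        assert np.allclose(st_fast.u, st_ref.u, rtol=1e-10, atol=1e-10)
        assert np.allclose(st_fast.W_rec.data, st_ref.W_rec.data, rtol=1e-10)
        assert np.allclose(st_fast.W_ff, st_ref.W_ff, rtol=1e-10)

    def test_divergence_raises_informative_error(self, small_net):
        p, conn, state = small_net
        state.u[:] = np.nan
        with pytest.raises(nw.NumericalDivergenceError):
            simulate_span(state, np.zeros(p.nI), 0.05, p, conn)


class TestInitState:
    def test_initial_weight_distribution(self, default_params):
        rng = np.random.default_rng(3)
        conn = build_connectivity(default_params, rng)
        state = init_state(default_params, conn, rng)
        d = default_params.derived()
        assert np.allclose(state.W_rec.data, 0.25 * d.w_hat_rec)
        existing = state.W_ff[conn.c_ff]
        assert existing.mean() == pytest.approx(0.35 * d.w_hat_ff, rel=0.05)
        assert existing.max() <= 0.7 * d.w_hat_ff
        assert np.all(state.W_ff[~conn.c_ff] == 0.0)
        assert np.all(state.u == 0.0) and state.u_inh == 0.0
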