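import numpy as np
import pytest

from engramnet.population import (PopulationParams, STATE_VARS, _F, basin_map,
                                  ff_change_map, find_fixed_points,
                                  integrate_population,
                                  population_derivatives)


@pytest.fixture(scope="module")
def pop():
    return PopulationParams()


def swap_populations(y):
    """Exchange populations 1<->2 (and their weights) in a state vector."""
    out = np.array(y, copy=True)
    out[..., [0, 1]] = out[..., [1, 0]]
    out[..., [3, 4]] = out[..., [4, 3]]
    out[..., [5, 6, 7, 8]] = out[..., [7, 8, 5, 6]]
    return out


class TestDerivatives:
    def test_zero_state_zero_input(self, pop):
        """Potentials stay put; weights drift only through the tiny baseline
        rate F(0) ~ 0.15 Hz, bounded by mu * F(0)^2."""
        dy = population_derivatives(np.zeros(9), (0.0, 0.0), pop)
        f0 = _F(0.0, pop)
        assert dy[0] == pytest.approx(-pop.R * pop.w_inh_out * f0)
        assert np.all(dy[3:] >= 0.0)
        assert np.all(dy[3:] <= pop.mu * f0**2 + 1e-12)

    def test_exchange_symmetry(self, pop):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 100, size=9)
        dy = population_derivatives(y, (130.0, 130.0), pop)
        dy_sw = population_derivatives(swap_populations(y), (130.0, 130.0), pop)
        assert np.allclose(swap_populations(dy), dy_sw)

    def test_recurrent_weight_fixed_point_at_saturation(self, pop):
        y = np.zeros(9)
        y[0] = 1e4                      # F1 = alpha
        y[3] = pop.w_hat_rec()
        dy = population_derivatives(y, (0.0, 0.0), pop)
        assert dy[3] == pytest.approx(0.0, abs=1e-9)


class TestIntegration:
    def test_zero_input_settles_at_low_activity(self, pop):
        y0 = np.zeros(9)
        y0[3] = y0[4] = 0.25 * pop.w_hat_rec()
        y = integrate_population(y0, (0.0, 0.0), pop, T=100.0)
        assert _F(y[0], pop) < 1.0 and _F(y[1], pop) < 1.0

    def test_slight_asymmetry_selects_one_population(self, pop):
        """Input A at 130 Hz with a small feed-forward advantage for
        population 1: it is potentiated to the balance weight while the
        loser's recurrent weight stays around a tenth of the winner's."""
        y0 = np.zeros(9)
        y0[3] = y0[4] = 0.25 * pop.w_hat_rec()
        y0[5] = 0.37 * pop.w_hat_ff()
        y0[7] = 0.33 * pop.w_hat_ff()
        y = integrate_population(y0, (130.0, 0.0), pop, T=300.0)
        assert y[3] == pytest.approx(pop.w_hat_rec(), rel=0.02)
        assert y[4] < 0.15 * y[3]   # ~10% at the underlying fixed point

    def test_symmetric_trajectory_stays_symmetric(self, pop):
        y0 = np.zeros(9)
        y0[3] = y0[4] = 20.0
        y0[5] = y0[7] = 100.0
        _, traj = integrate_population(y0, (130.0, 0.0), pop, T=2.0,
                                       record_every=50)
        assert np.allclose(traj[:, 0], traj[:, 1])
        assert np.allclose(traj[:, 3], traj[:, 4])

    def test_invalid_duration_rejected(self, pop):
        with pytest.raises(ValueError):
            integrate_population(np.zeros(9), (0.0, 0.0), pop, T=-1.0)


@pytest.fixture(scope="module")
def fps_130(pop):
    return find_fixed_points(pop, inputs=(130.0, 0.0))


class TestFixedPoints:

    def test_structure_at_working_amplitude(self, fps_130):
        """At 130 Hz: two stable asymmetric (assembly) states and a saddle
        on the identity line, as in the published phase portrait."""
        stable_asym = [f for f in fps_130
                       if f.stability == "stable" and f.label in ("pop1", "pop2")]
        saddles_sym = [f for f in fps_130
                       if f.stability == "saddle"
                       and abs(f.state[0] - f.state[1]) < 1e-6]
        assert len(fps_130) >= 3
        assert len(stable_asym) == 2
        assert len(saddles_sym) >= 1

    def test_loser_recurrent_weight_about_tenth(self, fps_130):
        pop1 = next(f for f in fps_130 if f.label == "pop1")
        assert pop1.state[4] / pop1.state[3] == pytest.approx(0.075, abs=0.05)

    def test_residuals_tiny_and_eigenvalue_signs_consistent(self, fps_130):
        for f in fps_130:
            assert f.residual < 1e-8
            re = f.eigenvalues.real
            if f.stability == "stable":
                assert np.all(re < 0)
            elif f.stability == "saddle":
                assert re.max() > 0 > re.min()

    def test_mirror_symmetry_of_fixed_point_set(self, pop, fps_130):
        states = np.array([f.state for f in fps_130])
        for f in fps_130:
            mirrored = swap_populations(f.state)
            dist = np.min(np.linalg.norm(states - mirrored, axis=1))
            assert dist < 1e-5 * max(1.0, np.linalg.norm(mirrored))

    def test_single_low_state_without_input(self, pop):
        fps = find_fixed_points(pop, inputs=(0.0, 0.0))
        assert len(fps) == 1
        assert fps[0].stability == "stable" and fps[0].label == "low"
        assert _F(fps[0].state[0], pop) < 1.0

    def test_steady_state_matches_long_integration(self, pop):
        """Independent cross-check: integrating the full nine ODEs from near
        an asymmetric fixed point stays on it."""
        fps = find_fixed_points(pop, inputs=(130.0, 0.0))
        pop1 = next(f for f in fps if f.label == "pop1"
                    and f.stability == "stable")
        y = integrate_population(pop1.state + 1e-3, (130.0, 0.0), pop, T=20.0)
        assert np.allclose(y, pop1.state, rtol=1e-4, atol=1e-3)


class TestFFChangeMap:
    def test_four_cases(self, pop):
        """Potentiation needs pre and post both high; silent input with an
        active target depresses; a suppressed target blocks changes."""
        f_suppressed = _F(-73.0, pop)      # rate of an inhibited population
        m = ff_change_map([0.0, 130.0], [f_suppressed, 100.0],
                          w0=0.35 * pop.w_hat_ff(), p=pop)
        case = {(0, 0): m["case"][0, 0], (0, 1): m["case"][0, 1],
                (1, 0): m["case"][1, 0], (1, 1): m["case"][1, 1]}
        assert case[(1, 1)] == "II" and m["delta_w"][1, 1] > 0
        assert case[(0, 1)] == "I" and m["delta_w"][0, 1] < 0
        assert case[(0, 0)] == "III" and case[(1, 0)] == "IV"
        assert abs(m["delta_w"][0, 0]) < 0.05 * pop.w_hat_ff()
        assert abs(m["delta_w"][1, 0]) < 0.05 * pop.w_hat_ff()


@pytest.fixture(scope="module")
def small_map(pop):
    return basin_map(pop,
                     ff_grid=np.linspace(0, pop.w_hat_ff(), 9),
                     rec_grid=np.linspace(0, pop.w_hat_rec(), 9))


class TestBasinMap:

    def test_dominant_initial_advantage_wins(self, small_map):
        assert small_map["winner"][-1, -1] == "pop1"

    def test_weak_population_one_loses(self, small_map):
        assert small_map["winner"][0, 0] == "pop2"

    def test_both_outcomes_present_with_boundary(self, small_map):
        w = small_map["winner"]
        assert (w == "pop1").any() and (w == "pop2").any()

    def test_exactly_symmetric_start_sits_on_boundary(self, pop):
        """With identical initial weights for both populations the dynamics
        cannot break the tie: both or neither end active."""
        b = basin_map(pop, ff_grid=[0.35 * pop.w_hat_ff()],
                      rec_grid=[0.25 * pop.w_hat_rec()],
                      w2A_frac=0.35, w2_rec_frac=0.25)
        assert b["winner"][0, 0] in ("none", "both")
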