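import numpy as np
import pytest

from fractcm import (
    ConfigurationError,
    ErlangDensity,
    ErlangTCMParameters,
    FractionalTCMParameters,
    GrowthParameters,
    MLDelayParameters,
    MittagLefflerDensity,
    PointDelay,
    SolverConfig,
    build_erlang_system,
    build_fractional_system,
    k_in,
    k_out,
    simulate_convolution_tcm,
    simulate_erlang,
    simulate_fractional,
    solve_multiorder,
    total_mass,
)

from .conftest import FITTED_FRACTIONAL


class TestGrowthKill:
    def test_exponential_regime(self, growth):
        # far below threshold the switch term is negligible: k_in ~ lambda0*u
        val = k_in(0.0121, 0.0121, growth)
        assert val == pytest.approx(0.25 * 0.0121, rel=1e-12)

    def test_threshold_value(self, growth):
        # at w = lambda1/lambda0 the switch term equals 1
        u = 0.5
        val = k_in(u, growth.threshold, growth)
        assert val == pytest.approx(0.25 * u * 2 ** (-1 / 20), rel=1e-12)

    def test_linear_regime_limit(self, growth):
        # w >> threshold: growth tends to lambda1 * u / w
        u = 1.0
        for w in (50.0, 500.0):
            assert k_in(u, w, growth) == pytest.approx(0.4603 * u / w, rel=1e-3)

    def test_no_overflow_at_large_phi_and_mass(self):
        g = GrowthParameters(phi=80.0)
        assert np.isfinite(k_in(1.0, 1e6, g))

    def test_negative_mass_rejected(self, growth):
        with pytest.raises(ValueError):
            k_in(-1.0, 1.0, growth)

    def test_kill_flux(self):
        assert k_out(0.0, 1.0, 0.5) == 0.0
        assert k_out(100.0, 1.0, 0.24657) == pytest.approx(24.657)
        assert k_out(2 * 3.0, 1.2, 0.4) == pytest.approx(2 * k_out(3.0, 1.2, 0.4))
        with pytest.raises(ValueError):
            k_out(-1.0, 1.0, 0.5)

    def test_small_phi_warns(self):
        with pytest.warns(UserWarning):
            GrowthParameters(phi=5.0)


class TestErlangSystem:
    def test_drug_free_reduces_to_pure_growth(self, growth):
        p = ErlangTCMParameters(growth=growth, eta=0.3, k1=0.5, n=1)
        cfg = SolverConfig(0, 15, 2**-5)
        traj = simulate_erlang(p, lambda t: 0.0 * t, cfg)
        assert np.all(traj.state("y1") == 0.0)
        w = total_mass(traj)
        assert np.all(np.diff(w) > 0)  # monotone growth
        # well below the threshold w_th = 1.84 g the growth is exponential
        assert w[-1] == pytest.approx(0.0121 * np.exp(0.25 * 15), rel=1e-3)

    def test_damaged_total_identity(self, growth, concentration):
        # d(sum y_i)/dt == k_out - k1*y_n algebraically, at random states
        p = ErlangTCMParameters(growth=growth, eta=0.37847, k1=0.54379, n=4)
        sys = build_erlang_system(p, concentration)
        rng = np.random.default_rng(7)
        for _ in range(100):
            state = rng.uniform(0.01, 2.0, size=5)
            t = rng.uniform(0, 40)
            dy = sys.rhs(t, state)
            lhs = dy[1:].sum()
            rhs = p.eta * concentration(t) * state[0] - p.k1 * state[-1]
            assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-15)

    def test_initial_state(self, erlang_params, concentration):
        sys = build_erlang_system(erlang_params, concentration)
        assert np.allclose(sys.initial_state, [0.0121, 0, 0, 0, 0])

    def test_matches_convolution_oracle(self, growth, concentration):
        # linear chain trick <-> convolution with Erlang density
        p = ErlangTCMParameters(growth=growth, eta=0.37847, k1=0.54379, n=4)
        cfg = SolverConfig(0, 30, 2**-6)
        chain = total_mass(simulate_erlang(p, concentration, cfg))
        conv = total_mass(simulate_convolution_tcm(
            growth, p.eta, ErlangDensity(p.n, p.k1), concentration, cfg))
        assert np.max(np.abs(chain - conv)) < 1e-3

    def test_equivalence_random_parameter_draws(self, growth, concentration):
        rng = np.random.default_rng(11)
        cfg = SolverConfig(0, 25, 2**-5)
        for _ in range(5):
            p = ErlangTCMParameters(growth=growth,
                                    eta=float(rng.uniform(0.05, 0.5)),
                                    k1=float(rng.uniform(0.2, 2.0)),
                                    n=int(rng.integers(1, 6)))
            chain = total_mass(simulate_erlang(p, concentration, cfg))
            conv = total_mass(simulate_convolution_tcm(
                growth, p.eta, ErlangDensity(p.n, p.k1), concentration, cfg))
            assert np.max(np.abs(chain - conv)) < 2e-3


class TestFractionalSystem:
    def test_structure_and_initial_state(self, fractional_params, concentration):
        sys = build_fractional_system(fractional_params, concentration)
        assert list(sys.state_names) == ["u", "z", "y"]
        assert np.allclose(sys.orders, [1.0, 0.945, 1.0])
        assert np.allclose(sys.initial_state, [0.0121, 0.0, 0.0])

    def test_alpha_bounds_enforced(self, growth):
        with pytest.raises(ValueError):
            FractionalTCMParameters(growth=growth, eta=0.1,
                                    delay=MLDelayParameters(1.0, 2.0))

    def test_drug_free_latent_states_stay_zero(self, fractional_params):
        cfg = SolverConfig(0, 15, 2**-5)
        traj = simulate_fractional(fractional_params, lambda t: 0.0 * t, cfg)
        assert np.all(traj.state("z") == 0.0)
        assert np.all(traj.state("y") == 0.0)
        assert np.all(np.diff(traj.state("u")) > 0)

    def test_regrowth_after_dosing_stops(self, fractional_params,
                                         concentration, cfg_coarse):
        # tumors begin to increase once the ten-day regimen ends on day 23
        traj = simulate_fractional(fractional_params, concentration, cfg_coarse)
        w = total_mass(traj)
        t = traj.t
        i23, iend = np.searchsorted(t, 23.0), len(t) - 1
        nadir = i23 + np.argmin(w[i23:])
        assert t[nadir] > 23.0
        assert w[iend] > 2 * w[nadir]

    def test_nonnegative_masses_along_trajectory(self, fractional_params,
                                                 concentration, cfg_coarse):
        traj = simulate_fractional(fractional_params, concentration, cfg_coarse)
        assert np.all(traj.state("u") >= 0)
        assert np.all(traj.state("y") >= -1e-12)

    def test_matches_convolution_oracle(self, growth, concentration):
        f = FITTED_FRACTIONAL
        p = FractionalTCMParameters(
            growth=growth, eta=f["eta"],
            delay=MLDelayParameters(f["alpha"], f["tau"]))
        cfg = SolverConfig(0, 30, 2**-6)
        semi = total_mass(simulate_fractional(p, concentration, cfg))
        conv = total_mass(simulate_convolution_tcm(
            growth, p.eta, MittagLefflerDensity(p.delay), concentration, cfg))
        assert np.max(np.abs(semi - conv)) < 1e-2

    def test_exponential_limit_matches_single_compartment_chain(
            self, growth, concentration):
        # alpha -> 1: ML delay degenerates to exponential = Erlang(n=1, 1/tau)
        tau = 3.6852
        pf = FractionalTCMParameters(growth=growth, eta=0.24657,
                                     delay=MLDelayParameters(0.999, tau))
        pe = ErlangTCMParameters(growth=growth, eta=0.24657, k1=1 / tau, n=1)
        cfg = SolverConfig(0, 40, 2**-6)
        wf = total_mass(simulate_fractional(pf, concentration, cfg))
        we = total_mass(simulate_erlang(pe, concentration, cfg))
        assert np.max(np.abs(wf - we)) / np.max(np.abs(we)) < 0.01


class TestConvolutionOracle:
    def test_point_delay_without_drug_stays_zero(self, growth):
        cfg = SolverConfig(0, 10, 2**-5)
        traj = simulate_convolution_tcm(growth, 0.5, PointDelay(2.0),
                                        lambda t: 0.0 * t, cfg)
        assert np.all(traj.state("y") == 0.0)

    def test_point_delay_is_lagged_erlang_limit(self, growth, concentration):
        # a DDE with lag T: y holds exactly the kills of the last T days
        cfg = SolverConfig(0, 30, 2**-6)
        traj = simulate_convolution_tcm(growth, 0.2, PointDelay(3.0),
                                        concentration, cfg)
        w = total_mass(traj)
        assert np.all(np.isfinite(w))
        assert np.all(traj.state("y") >= -1e-12)

    def test_negative_point_delay_rejected(self):
        with pytest.raises(ValueError):
            PointDelay(-1.0)

    def test_non_normalized_density_rejected(self, growth, concentration):
        class Bogus:
            def survival(self, t):
                return 0.5 * np.exp(-np.asarray(t))  # S(0) = 0.5

        with pytest.raises(ConfigurationError):
            simulate_convolution_tcm(growth, 0.3, Bogus(), concentration,
                                     SolverConfig(0, 5, 2**-4))

    def test_drug_free_mass_conservation_form(self, growth):
        # eta = 0: w = u grows, y identically zero, in the convolution form too
        cfg = SolverConfig(0, 15, 2**-5)
        traj = simulate_convolution_tcm(growth, 0.0, ErlangDensity(3, 0.5),
                                        lambda t: 0.0 * t, cfg)
        assert np.all(traj.state("y") == 0.0)
        assert np.all(np.diff(total_mass(traj)) > 0)


def test_delay_monotonic_in_tau_and_alpha(growth, concentration):
    """Longer time scale tau, or smaller order alpha near the exponential
    regime, both delay the post-treatment nadir."""
    cfg = SolverConfig(0, 45, 2**-6)
    i13 = int(13 / cfg.step)

    def nadir(alpha, tau):
        p = FractionalTCMParameters(growth=growth, eta=0.24657,
                                    delay=MLDelayParameters(alpha, tau))
        traj = simulate_fractional(p, concentration, cfg)
        w = total_mass(traj)
        return traj.t[i13 + np.argmin(w[i13:])]

    taus = [1.5, 2.5, 3.685, 5.0, 7.0]
    n_tau = [nadir(0.945, tau) for tau in taus]
    assert all(b >= a for a, b in zip(n_tau, n_tau[1:]))

    alphas = [0.86, 0.89, 0.92, 0.95, 0.98]
    n_alpha = [nadir(a, 3.6852) for a in alphas]
    assert all(b <= a for a, b in zip(n_alpha, n_alpha[1:]))
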