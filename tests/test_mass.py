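"""Single-population and E-I mean-field dynamics."""

import numpy as np
import pytest
from massfield import (
    EIParams,
    MassParams,
    ei_fixed_point,
    ei_rhs,
    filtered_pulse,
    from_kuramoto,
    make_pulse,
    mass_fixed_points,
    mass_jacobian,
    mass_rhs,
    simulate_ei,
    simulate_mass,
    to_kuramoto,
)
from massfield.mass import make_ei_rhs
from massfield.params import ParameterError


class TestConformalMap:
    def test_perfect_asynchrony(self):
        tau = 15.0
        assert to_kuramoto(1.0 / (np.pi * tau), 0.0, tau) == pytest.approx(0.0)

    def test_full_synchrony_at_rest(self):
        assert to_kuramoto(0.0, 0.0, 10.0) == pytest.approx(1.0)

    def test_inverse_consistency(self, rng):
        """The Moebius map and its algebraic inverse round-trip to 1e-12."""
        tau = 12.0
        R = rng.uniform(1e-3, 1.0, 1000)
        V = rng.uniform(-3.0, 3.0, 1000)
        Z = to_kuramoto(R, V, tau)
        R2, V2 = from_kuramoto(Z, tau)
        np.testing.assert_allclose(R2, R, atol=1e-12, rtol=0)
        np.testing.assert_allclose(V2, V, atol=1e-12, rtol=0)

    def test_unit_disc(self, rng):
        """R >= 0 maps inside the closed unit disc."""
        Z = to_kuramoto(rng.uniform(0, 2, 500), rng.uniform(-5, 5, 500), 8.0)
        assert np.all(np.abs(Z) <= 1 + 1e-12)


class TestMassFixedPoints:
    def test_rate_zero_is_repelled(self):
        p = MassParams()
        dR = mass_rhs([0.0, -1.0, 0.0, 0.0], p)[0]
        assert dR == pytest.approx(p.gamma / (np.pi * p.tau**2))
        assert dR > 0

    def test_steady_synapse_equals_rate(self):
        # Q applied to a constant is the identity, so U0 = R0
        for fp in mass_fixed_points(MassParams(eta0=2.0)):
            assert fp.state[2] == pytest.approx(fp.state[0])

    def test_derivatives_vanish_at_fixed_points(self, rng):
        """Root-finder oracle: rhs residual below 1e-10 at every root."""
        for _ in range(100):
            p = MassParams(
                eta0=rng.uniform(-2, 4), gamma=rng.uniform(0.1, 1.5),
                tau=rng.uniform(5, 25), kappa_v=rng.uniform(0, 2),
                kappa_s=rng.uniform(-3, 3), alpha=rng.uniform(0.05, 1.0))
            for fp in mass_fixed_points(p):
                assert np.max(np.abs(mass_rhs(fp.state, p))) < 1e-10

    def test_uncoupled_fixed_point_relations(self):
        """With kappa_s = kappa_v = 0 the steady state satisfies the
        uncoupled fixed-point relations."""
        p = MassParams(eta0=1.5, kappa_s=0.0, kappa_v=0.0)
        for fp in mass_fixed_points(p):
            R0, V0 = fp.R, fp.V
            assert V0 == pytest.approx(-p.gamma / (2 * np.pi * p.tau * R0))
            assert p.eta0 + V0**2 == pytest.approx((np.pi * p.tau * R0) ** 2)

    def test_eigenvalues_match_finite_difference_jacobian(self, rng):
        p = MassParams(eta0=1.0, kappa_v=0.8)
        fp = mass_fixed_points(p)[-1]
        h = 1e-7
        J_fd = np.empty((4, 4))
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            J_fd[:, j] = (mass_rhs(fp.state + e, p) - mass_rhs(fp.state - e, p)) / (2 * h)
        np.testing.assert_allclose(mass_jacobian(fp.state, p), J_fd, atol=1e-6)
        ev = np.sort_complex(np.linalg.eigvals(J_fd))
        np.testing.assert_allclose(np.sort_complex(fp.eigenvalues), ev, atol=1e-6)

    def test_fixed_point_count_bounded(self, rng):
        for _ in range(50):
            p = MassParams(eta0=rng.uniform(-3, 3), kappa_s=rng.uniform(-5, 5),
                           kappa_v=rng.uniform(0, 2))
            assert 0 <= len(mass_fixed_points(p)) <= 4


class TestFilteredPulse:
    def test_zero_filter_limit_is_square(self):
        t = np.linspace(-50, 500, 1101)
        interior = (np.abs(t) > 1e-9) & (np.abs(t - 400.0) > 1e-9)
        sharp = filtered_pulse(t, 0.0, 400.0, 3.0, tau_f=1e-9)
        square = np.where((t >= 0) & (t < 400), 3.0, 0.0)
        np.testing.assert_allclose(sharp[interior], square[interior], atol=1e-6)

    def test_unit_mass_convolution_preserves_integral(self):
        t = np.linspace(-200, 3000, 320001)
        for tau_f in (10.0, 50.0, 120.0):
            A = filtered_pulse(t, 0.0, 400.0, 3.0, tau_f)
            integral = np.trapezoid(A, t)
            assert integral == pytest.approx(3.0 * 400.0, rel=1e-4)

    def test_step_response_closed_form(self):
        val = filtered_pulse(400.0 - 1e-12, 0.0, 400.0, 3.0, tau_f=50.0)
        assert val == pytest.approx(3.0 * (1 - np.exp(-8.0)), rel=1e-9)


class TestSimulateMass:
    def test_limit_cycle_and_synchrony_peaks_coincide(self, single_pop_osc):
        """In the oscillatory regime the R and |Z| peaks roughly align."""
        from scipy.signal import find_peaks

        tr = simulate_mass(single_pop_osc, T=3000, dt=0.5)
        sel = tr.t > 1500
        t, R, aZ = tr.t[sel], tr.R[sel], np.abs(tr.Z[sel])
        assert R.max() - R.min() > 1e-3  # sustained oscillation
        pR, _ = find_peaks(R, prominence=0.1 * (R.max() - R.min()))
        pZ, _ = find_peaks(aZ, prominence=0.1 * (aZ.max() - aZ.min()))
        tR, tZ = t[pR], t[pZ]
        offsets = [np.min(np.abs(tZ - x)) for x in tR]
        period = np.mean(np.diff(tR))
        assert np.mean(offsets) < period / 10

    def test_converges_below_hopf(self, single_pop_osc):
        p = single_pop_osc.replace(kappa_v=0.5)
        fp = mass_fixed_points(p)[-1]
        tr = simulate_mass(p, T=4000, dt=1.0)
        assert np.abs(tr.R[-1] - fp.R) < 1e-6
        assert fp.stable

    def test_positivity_and_bounded_synchrony(self, single_pop_osc):
        tr = simulate_mass(single_pop_osc, s0=[0.2, 1.0, 0.0, 0.0], T=2000, dt=1.0)
        assert np.all(tr.R >= 0)
        assert np.all(np.abs(tr.Z) <= 1 + 1e-9)

    def test_period_converges_under_step_refinement(self, single_pop_osc):
        from massfield.observables import oscillation_extrema

        periods = []
        for rtol in (1e-6, 1e-9):
            tr = simulate_mass(single_pop_osc, T=4000, dt=0.5, rtol=rtol)
            _, _, per = oscillation_extrema(tr.R, tr.t, 0.5)
            periods.append(per)
        assert abs(periods[1] - periods[0]) / periods[1] < 1e-3


class TestEIModel:
    def test_exchange_symmetry(self):
        """Identical populations with identical states stay synchronised."""
        p = EIParams(eta0_E=2.0, eta0_I=2.0, kappa_v_E=0.4, kappa_v_I=0.4,
                     kappa_s_EE=5.0, kappa_s_EI=5.0, kappa_s_IE=5.0, kappa_s_II=5.0,
                     alpha_EE=0.3, alpha_EI=0.3, alpha_IE=0.3, alpha_II=0.3)
        y = np.array([0.3, -0.5, 0.3, -0.5] + [0.2, 0.01] * 4)
        d = ei_rhs(y, p)
        np.testing.assert_allclose(d[:2], d[2:4], atol=1e-14)
        tr = simulate_ei(p, s0=y, T=100, dt=0.05)
        np.testing.assert_allclose(tr.y[0], tr.y[2], atol=1e-8)

    def test_decoupled_reduces_to_single_population(self):
        p = EIParams(kappa_s_EE=0.0, kappa_s_EI=0.0, kappa_s_IE=0.0, kappa_s_II=0.0)
        y = np.array([0.4, -0.2, 0.7, 0.1] + [0.0, 0.0] * 4)
        d = ei_rhs(y, p)
        dE = mass_rhs([0.4, -0.2, 0.0, 0.0],
                      MassParams(eta0=p.eta0_E, gamma=p.gamma_E, tau=p.tau_E,
                                 kappa_v=p.kappa_v_E, kappa_s=0.0, alpha=1.0))
        np.testing.assert_allclose(d[:2], dE[:2], rtol=1e-14, atol=1e-15)

    def test_fixed_point_residual(self, ei_inhibitory_gaps):
        p = ei_inhibitory_gaps.replace(eta0_I=-10.0)
        fp = ei_fixed_point(p)
        assert np.max(np.abs(ei_rhs(fp, p))) < 1e-9

    def test_bursting_regime(self):
        """Strong within-population gap junctions give slow bursts of fast,
        high-amplitude firing separated by quiescent epochs."""
        p = EIParams()  # seizure-like bursting regime
        fp = ei_fixed_point(p)
        tr = simulate_ei(p, s0=fp + 1e-2, T=600, dt=0.05)
        t, RE = tr.t, tr.y[0]
        sel = t > 200
        t, RE = t[sel], RE[sel]
        assert RE.max() > 3.0  # high amplitude
        bins = ((t - t[0]) // 2.0).astype(int)
        env = np.array([RE[bins == b].max() for b in range(bins.max() + 1)])
        quiet = env < 0.2 * env.max()
        # at least two quiescent epochs longer than 20 ms
        runs, n = [], 0
        for q in quiet:
            n = n + 1 if q else (runs.append(n) or 0 if n else 0)
        if n:
            runs.append(n)
        assert sum(1 for r in runs if r * 2.0 >= 20.0) >= 2
        # synchrony is tracked through the bursts
        aZE = np.abs(tr.Z_E[sel])
        assert aZE.max() - aZE.min() > 0.1

    def test_derivatives_vanish_at_ei_fixed_point(self, ei_inhibitory_gaps):
        fp = ei_fixed_point(ei_inhibitory_gaps.replace(eta0_I=5.0))
        assert np.max(np.abs(ei_rhs(fp, ei_inhibitory_gaps.replace(eta0_I=5.0)))) < 1e-9

    def test_tolerance_refinement_consistency(self):
        p = EIParams()
        fp = ei_fixed_point(p)
        trs = [simulate_ei(p, s0=fp + 1e-2, T=50, dt=0.02, rtol=rt, atol=1e-12)
               for rt in (1e-8, 1e-10)]
        scale = np.abs(trs[1].y).max()
        rms = np.sqrt(np.mean((trs[0].y - trs[1].y) ** 2))
        assert rms / scale < 1e-3

    def test_rate_positivity(self, ei_inhibitory_gaps):
        tr = simulate_ei(ei_inhibitory_gaps.replace(eta0_I=-3.0), T=300, dt=0.05)
        assert np.all(tr.y[0] >= 0) and np.all(tr.y[2] >= 0)
        assert np.all(np.abs(tr.Z_E) <= 1 + 1e-9)

    def test_fast_rhs_matches_reference(self, rng):
        p = EIParams(eta0_I=-5.0)
        y = rng.uniform(-1, 1, 12)
        np.testing.assert_array_equal(make_ei_rhs(p)(0.0, y), ei_rhs(y, p))


class TestParamValidation:
    def test_bad_gamma(self):
        with pytest.raises(ParameterError):
            MassParams(gamma=0.0)

    def test_bad_reset_order(self):
        from massfield import NetworkParams
        with pytest.raises(ParameterError):
            NetworkParams(v_r=10.0, v_th=-10.0)
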