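"""Delayed neural field: convolution quadrature, solver, reductions."""

import numpy as np
import pytest

from massfield import MassParams, simulate_mass
from massfield.field import (
    DelayedConvolution,
    FieldState,
    delayed_drive,
    make_initial_condition,
    simulate_field,
)
from massfield.kernels import transfer_function
from massfield.params import FieldParams
from massfield.stability import leading_eigenvalue, uniform_steady_state


@pytest.fixture(scope="module")
def p1d(field_mass_1d):
    return FieldParams(mass=field_mass_1d, c=1.0, dim=1, L=40 * np.pi, n=256)


def _cos_history(conv, p, k, n_extra=1, time_factor=None):
    x = np.arange(p.n) * p.dx
    nh = conv.max_steps + 1 + n_extra
    base = np.cos(k * x)
    if time_factor is None:
        return np.broadcast_to(base, (nh,) + base.shape).copy()
    tpast = -(np.arange(nh)[::-1]) * conv.dt
    return time_factor(tpast)[:, None] * base[None, :]


class TestDelayedConvolution:
    def test_discrete_balance_annihilates_constants(self, p1d):
        conv = DelayedConvolution(p1d, p1d.step)
        hist = np.ones((conv.max_steps + 2, p1d.n)) * 0.37
        psi = conv.apply_direct(hist)
        assert np.max(np.abs(psi)) < 1e-12

    def test_frozen_plane_wave_matches_static_transfer(self, p1d):
        conv = DelayedConvolution(p1d, p1d.step)
        for kidx in (5, 20):
            k = 2 * np.pi * kidx / p1d.L
            hist = _cos_history(conv, p1d, k)
            psi = delayed_drive(hist, p1d, p1d.step)
            target = np.cos(k * np.arange(p1d.n) * p1d.dx)
            ratio = psi @ target / (target @ target)
            G = transfer_function(k, 0.0, p1d.c, 1).real
            assert ratio == pytest.approx(G, abs=5e-3)

    def test_growing_wave_matches_transfer_at_real_rate(self, p1d):
        conv = DelayedConvolution(p1d, p1d.step)
        k = 2 * np.pi * 10 / p1d.L
        sigma = 0.02
        hist = _cos_history(conv, p1d, k, time_factor=lambda t: np.exp(sigma * t))
        psi = delayed_drive(hist, p1d, p1d.step)
        target = np.cos(k * np.arange(p1d.n) * p1d.dx)
        ratio = psi @ target / (target @ target)
        G = transfer_function(k, sigma, p1d.c, 1).real
        assert abs(ratio - G) / abs(G) < 0.01

    def test_fft_path_equals_direct_reference_1d(self, p1d):
        rng = np.random.default_rng(1)
        conv = DelayedConvolution(p1d, p1d.step)
        hist = 0.02 + 0.005 * rng.standard_normal((conv.max_steps + 2, p1d.n))
        psi_fft = delayed_drive(hist, p1d, p1d.step, method="fft")
        psi_dir = delayed_drive(hist, p1d, p1d.step, method="direct")
        np.testing.assert_allclose(psi_fft, psi_dir, atol=1e-12)

    def test_fft_path_equals_direct_reference_2d(self, field_mass_1d):
        p = FieldParams(mass=field_mass_1d, c=1.0, dim=2, n=16, L=12.0)
        rng = np.random.default_rng(2)
        conv = DelayedConvolution(p, p.step)
        hist = 0.02 + 0.005 * rng.standard_normal((conv.max_steps + 2, p.n, p.n))
        psi_fft = delayed_drive(hist, p, p.step, method="fft")
        psi_dir = delayed_drive(hist, p, p.step, method="direct")
        np.testing.assert_allclose(psi_fft, psi_dir, atol=1e-12)

    def test_infinite_speed_reduces_to_plain_convolution(self, field_mass_1d):
        """c -> infinity with a static field: all delays collapse to zero."""
        p_fast = FieldParams(mass=field_mass_1d, c=1e6, dim=1, L=40 * np.pi, n=128,
                             dt=0.15)
        rng = np.random.default_rng(3)
        R_now = 0.02 + 0.005 * rng.standard_normal(p_fast.n)
        conv = DelayedConvolution(p_fast, 0.15)
        assert conv.max_steps <= 1
        hist = np.broadcast_to(R_now, (conv.max_steps + 2, p_fast.n)).copy()
        psi = delayed_drive(hist, p_fast, 0.15)
        # oracle: direct static convolution with the same discrete weights
        w = conv._w_slices.sum(axis=0)
        psi_static = np.array([np.sum(w * R_now[(i - np.arange(p_fast.n)) % p_fast.n])
                               for i in range(p_fast.n)])
        np.testing.assert_allclose(psi, psi_static, atol=1e-6)

    def test_short_history_raises(self, p1d):
        with pytest.raises(ValueError, match="history too short"):
            delayed_drive(np.zeros((3, p1d.n)), p1d, p1d.step)


class TestInitialConditions:
    def test_zero_amplitude_is_exact_steady_state(self, p1d):
        ic = make_initial_condition(p1d, amplitude=0.0)
        tr = simulate_field(p1d, ic, T=10 * p1d.mass.tau, save_every=5.0)
        drift = np.abs(tr.R.astype(float) - ic.R[None, :]).max()
        assert drift < 1e-8

    def test_lattice_has_discrete_translation_symmetry(self, field_mass_1d):
        p = FieldParams(mass=field_mass_1d, c=1.0, dim=2, n=32, L=16.0)
        m_cells = 4
        ic = make_initial_condition(p, "periodic-lattice", amplitude=0.01,
                                    n_cells=m_cells)
        shift = p.n // m_cells
        np.testing.assert_allclose(ic.R, np.roll(ic.R, shift, axis=0), atol=1e-14)
        np.testing.assert_allclose(ic.R, np.roll(ic.R, shift, axis=1), atol=1e-14)

    def test_unknown_kind_rejected(self, p1d):
        with pytest.raises(ValueError, match="unknown initial-condition"):
            make_initial_condition(p1d, "vortex-soup")

    def test_cfl_guard(self, field_mass_1d):
        p = FieldParams(mass=field_mass_1d, c=1.0, dim=1, n=64, L=40.0, dt=5.0)
        from massfield.field import CFLError

        with pytest.raises(CFLError):
            simulate_field(p, T=1.0)


class TestFieldDynamics:
    def test_uniform_trajectory_follows_mass_model(self, field_mass_1d):
        """A uniform field sees no net synaptic drive, so every point follows
        the single-population model with the synapse disconnected.  A
        time-varying uniform state still feels the *delayed* zero mode
        (G(0, lambda) vanishes only at lambda = 0), so the exact reduction
        requires the instantaneous-interaction limit of large c."""
        p = FieldParams(mass=field_mass_1d, c=1e5, dim=1, n=64, L=40.0, dt=0.05)
        ic = make_initial_condition(p, amplitude=0.0)
        ic.V += 0.3  # uniform voltage kick
        ic.history[:] = ic.R
        tr = simulate_field(p, ic, T=150.0, save_every=1.0)
        m0 = p.mass.replace(kappa_s=0.0)
        s0 = [float(ic.R[0]), float(ic.V[0]), 0.0, 0.0]
        ref = simulate_mass(m0, s0=s0, T=150.0, dt=1.0, rtol=1e-10)
        spatial_spread = tr.R.astype(float).std(axis=1).max()
        assert spatial_spread < 1e-10
        np.testing.assert_allclose(tr.R[:, 0].astype(float), ref.R, atol=1e-5)

    def test_seeded_mode_growth_matches_dispersion(self, field_mass_1d):
        """Linear-regime oracle at two (k, kappa_v) points, 5% tolerance."""
        for kv, kidx in ((0.95, 20), (0.8, 10)):
            p = FieldParams(mass=field_mass_1d.replace(kappa_v=kv), c=1.0,
                            dim=1, L=40 * np.pi, n=256)
            k = 2 * np.pi * kidx / p.L
            lam = leading_eigenvalue(k, p)
            ic = make_initial_condition(p, "mode", amplitude=1e-5, mode_k=kidx)
            tr = simulate_field(p, ic, T=700.0, save_every=1.0)
            amp = np.abs(np.fft.rfft(tr.R.astype(float), axis=1))[:, kidx]
            period = 2 * np.pi / abs(lam.imag)
            w = max(3, int(round(period)))
            env = np.array([amp[i:i + w].max()
                            for i in range(0, len(amp) - w, w)])
            te = (np.arange(len(env)) + 0.5) * w
            sel = te > 200
            rate = np.polyfit(te[sel], np.log(env[sel]), 1)[0]
            assert rate == pytest.approx(lam.real, abs=0.05 * abs(lam.real) + 2e-5)

    def test_stable_regime_perturbations_decay(self, field_mass_1d):
        p = FieldParams(mass=field_mass_1d.replace(kappa_v=0.5), c=1.0, dim=1,
                        n=128, L=40 * np.pi)
        ic = make_initial_condition(p, "uniform+noise", amplitude=1e-3, seed=4)
        tr = simulate_field(p, ic, T=800.0, save_every=10.0)
        R = tr.R.astype(float)
        dev0 = np.abs(R[0] - R[0].mean()).max()
        dev1 = np.abs(R[-1] - R[-1].mean()).max()
        assert dev1 < 0.2 * dev0

    def test_rate_stays_nonnegative_and_synchrony_bounded(self, field_mass_1d):
        p = FieldParams(mass=field_mass_1d.replace(kappa_v=0.9), c=1.0, dim=1,
                        n=128, L=40 * np.pi)
        ic = make_initial_condition(p, "uniform+noise", amplitude=5e-3, seed=5)
        tr = simulate_field(p, ic, T=400.0, save_every=5.0)
        assert tr.R.min() >= 0
        assert np.all(np.abs(tr.Z) <= 1 + 1e-9)

    def test_final_state_continuation_is_seamless(self, field_mass_1d):
        p = FieldParams(mass=field_mass_1d.replace(kappa_v=0.9), c=1.0, dim=1,
                        n=64, L=40.0, dt=0.125)  # dt divides save_every
        ic = make_initial_condition(p, "uniform+noise", amplitude=5e-3, seed=6)
        one = simulate_field(p, ic, T=200.0, save_every=1.0)
        a = simulate_field(p, ic, T=100.0, save_every=1.0)
        b = simulate_field(p, a.final_state, T=100.0, save_every=1.0)
        np.testing.assert_allclose(b.R[-1].astype(float),
                                   one.R[-1].astype(float), atol=1e-6)


class TestWaveRegimes:
    """Saturated pattern classes of the 1D field near its instabilities.

    Each run seeds the relevant marginal structure (uniform kick, critical
    cosine mode, or one member of the travelling pair) so the slow
    near-threshold growth starts from a finite amplitude.
    """

    def test_slow_speed_bulk_oscillation(self, field_mass_1d):
        from massfield.observables import classify_pattern_1d

        p = FieldParams(mass=field_mass_1d, c=0.1, dim=1, L=40 * np.pi, n=256)
        ic = make_initial_condition(p, "mode", amplitude=5e-3, mode_k=0,
                                    noise=1e-5, seed=1)
        tr = simulate_field(p, ic, T=5000.0, save_every=4.0, save_start=3000.0)
        R = tr.R.astype(float)
        spat = R.var(axis=1).mean()
        temp = R.var(axis=0).mean()
        assert spat / temp < 1e-4  # spatially uniform oscillation
        assert classify_pattern_1d(R, 4.0, p.dx) == "bulk"

    def test_intermediate_speed_standing_wave(self, field_mass_1d):
        from massfield.observables import classify_pattern_1d
        from massfield.stability import dispersion_relation

        p = FieldParams(mass=field_mass_1d.replace(kappa_v=0.855), c=0.11,
                        dim=1, L=40 * np.pi, n=256)
        d = dispersion_relation(p, k_max=3.0, nk=61)
        kidx = int(round(d.k_star * p.L / (2 * np.pi)))
        ic = make_initial_condition(p, "mode", amplitude=5e-3, mode_k=kidx,
                                    noise=1e-5, seed=1)
        tr = simulate_field(p, ic, T=5000.0, save_every=4.0, save_start=3000.0)
        assert classify_pattern_1d(tr.R.astype(float), 4.0, p.dx) == "standing-wave"

    def test_fast_speed_travelling_wave(self, field_mass_1d):
        from massfield.observables import classify_pattern_1d
        from massfield.stability import dispersion_relation

        p = FieldParams(mass=field_mass_1d.replace(kappa_v=0.88), c=1.0,
                        dim=1, L=40 * np.pi, n=256)
        d = dispersion_relation(p, k_max=3.0, nk=61)
        kidx = int(round(d.k_star * p.L / (2 * np.pi)))
        ic = make_initial_condition(p, "travelling-mode", amplitude=5e-3,
                                    mode_k=kidx)
        tr = simulate_field(p, ic, T=5000.0, save_every=4.0, save_start=3000.0)
        assert classify_pattern_1d(tr.R.astype(float), 4.0, p.dx) == "travelling-wave"
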