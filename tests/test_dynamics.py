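import math

import numpy as np
import pytest

from bubston import dynamics as dyn
from bubston.errors import (
    DomainError,
    NoOscillationError,
    NoRealEigenfrequencyError,
)
from bubston.units import ELEMENTARY_CHARGE


def _q(n_e: float) -> float:
    return n_e * ELEMENTARY_CHARGE


class TestNaturalFrequency:
    def test_nanobubble_oscillates_in_the_GHz_range(self, water):
        w0 = dyn.natural_frequency(water, 1e-5, _q(-60))
        assert round(math.log10(w0)) == 9  # order 1e9 s^-1

    def test_minnaert_limit(self):
        # Gamma, eta, Q, P_v -> 0 reduces to (1/R0) sqrt(3 gamma P0 / rho)
        tiny = 1e-30
        medium = dyn.MediumProperties(gamma_surface=tiny, eta=tiny, P_v=tiny)
        R0 = 1e-5
        w0 = dyn.natural_frequency(medium, R0, 0.0)
        minnaert = math.sqrt(3.0 * medium.gamma_adiabatic * medium.P0 / medium.rho_l) / R0
        assert w0 == pytest.approx(minnaert, rel=1e-10)

    def test_small_charge_is_negligible_at_100nm(self, water):
        w_charged = dyn.natural_frequency(water, 1e-5, _q(-60))
        w_neutral = dyn.natural_frequency(water, 1e-5, 0.0)
        assert abs(w_charged - w_neutral) / w_neutral < 1e-4

    def test_overcharged_bubble_has_no_real_eigenfrequency(self, water):
        with pytest.raises(NoRealEigenfrequencyError) as exc:
            dyn.natural_frequency(water, 1e-6, _q(-1e6))
        assert exc.value.omega_sq < 0


class TestDampingCoefficient:
    def test_positive_with_finite_decay_time(self, water, charge_60e):
        for R0 in (5e-6, 1e-5, 2e-5):
            d = dyn.damping_coefficient(water, R0, -charge_60e)
            assert d.beta > 0
            assert d.tau == pytest.approx(1.0 / d.beta, rel=1e-15)

    def test_closed_form_attenuation_tracks_energy_decay(self, water, charge_60e):
        # the attenuation expression is ~2x the linearized amplitude decay rate
        beta = dyn.damping_coefficient(water, 1e-5, -charge_60e).beta
        beta_amp = dyn.amplitude_decay_rate(water, 1e-5, -charge_60e)
        assert beta / beta_amp == pytest.approx(2.0, rel=0.01)

    def test_domain(self, water):
        with pytest.raises(DomainError):
            dyn.damping_coefficient(water, -1e-5, 0.0)


class TestIntegration:
    def test_rest_state_stays_at_rest(self, water, charge_60e):
        R0 = 1e-5
        traj = dyn.integrate_radial_dynamics(
            R0, 0.0, R0, -charge_60e, water, t_span=(0.0, 50e-9), n_samples=500
        )
        assert np.max(np.abs(traj.R - R0)) < 1e-7 * R0

    @pytest.mark.parametrize("R0_nm", [75, 100])
    def test_ringdown_peak_matches_eigenfrequency(self, water, charge_60e, R0_nm):
        R0 = R0_nm * 1e-7
        w0 = dyn.natural_frequency(water, R0, -charge_60e)
        T = 2 * math.pi / w0
        traj = dyn.integrate_radial_dynamics(
            1.01 * R0, 0.0, R0, -charge_60e, water, t_span=(0.0, 12 * T), n_samples=6000
        )
        ring = dyn.extract_ringdown(traj)
        assert ring.omega_natural == pytest.approx(w0, rel=0.05)

    def test_envelope_decay_matches_linearized_rate(self, water, charge_60e):
        R0 = 1e-5
        w0 = dyn.natural_frequency(water, R0, -charge_60e)
        traj = dyn.integrate_radial_dynamics(
            1.01 * R0, 0.0, R0, -charge_60e, water,
            t_span=(0.0, 12 * 2 * math.pi / w0), n_samples=6000,
        )
        ring = dyn.extract_ringdown(traj)
        assert ring.beta == pytest.approx(dyn.amplitude_decay_rate(water, R0, -charge_60e), rel=0.10)

    def test_free_oscillation_amplitude_never_grows(self, water, charge_60e):
        R0 = 1e-5
        w0 = dyn.natural_frequency(water, R0, -charge_60e)
        traj = dyn.integrate_radial_dynamics(
            1.01 * R0, 0.0, R0, -charge_60e, water,
            t_span=(0.0, 10 * 2 * math.pi / w0), n_samples=5000,
        )
        x = np.abs(traj.R - R0)
        d = np.diff(traj.R - R0)
        ext = np.nonzero(d[:-1] * d[1:] < 0)[0] + 1
        peaks = x[ext]
        peaks = peaks[peaks > 1e-6 * x.max()]
        assert np.all(np.diff(peaks) < 0)

    def test_solver_tolerance_convergence(self, water, charge_60e):
        R0 = 1e-5
        w0 = dyn.natural_frequency(water, R0, -charge_60e)
        span = (0.0, 12 * 2 * math.pi / w0)
        omegas = []
        for rtol in (1e-9, 5e-10):
            traj = dyn.integrate_radial_dynamics(
                1.01 * R0, 0.0, R0, -charge_60e, water, t_span=span,
                rtol=rtol, n_samples=6000,
            )
            omegas.append(dyn.extract_ringdown(traj).omega_damped)
        assert abs(omegas[1] - omegas[0]) / omegas[0] < 1e-3

    def test_slow_drive_grows_bubble_in_reduced_pressure_phase(self, water, charge_60e):
        """A low-frequency pressure pulse inflates the bubble while the drive
        pressure is negative, and the bubble rings at its own frequency once
        the drive is gone (spectral-content check, not exact values)."""
        R0, Q = 1e-5, -charge_60e
        om = 1.2e8  # well below omega_0 ~ 8e8
        drive = dyn.AcousticDrive(P_s=5e5, omega=om)
        T_half = math.pi / om
        traj = dyn.integrate_radial_dynamics(
            R0, 0.0, R0, Q, water, drive=drive, t_span=(0.0, 2 * T_half), n_samples=3000
        )
        reduced = traj.t > T_half  # sin(om t) < 0: reduced far-field pressure
        assert traj.R[reduced].max() > R0 * 1.001
        assert traj.R[~reduced].max() <= R0 * (1 + 1e-6)
        # free decay from the post-pulse state rings near omega_0
        free = dyn.integrate_radial_dynamics(
            traj.R[-1], traj.Rdot[-1], R0, Q, water, t_span=(0.0, 100e-9), n_samples=5000
        )
        ring = dyn.extract_ringdown(free)
        w0 = dyn.natural_frequency(water, R0, Q)
        assert ring.omega_natural == pytest.approx(w0, rel=0.10)

    def test_nonfinite_parameters_rejected(self, water):
        with pytest.raises(DomainError):
            dyn.integrate_radial_dynamics(math.nan, 0.0, 1e-5, 0.0, water)


class TestExtractRingdown:
    def _damped_cosine(self, omega, beta, n=8000, periods=12):
        t = np.linspace(0.0, periods * 2 * math.pi / omega, n)
        R0 = 1e-5
        R = R0 * (1.0 + 0.01 * np.exp(-beta * t) * np.cos(omega * t))
        return dyn.RadialTrajectory(t=t, R=R, Rdot=np.gradient(R, t), metadata={"R0_cm": R0})

    def test_recovers_known_frequency_and_decay(self):
        omega, beta = 8e8, 5e7
        ring = dyn.extract_ringdown(self._damped_cosine(omega, beta))
        assert ring.omega_damped == pytest.approx(omega, rel=0.01)
        assert ring.beta == pytest.approx(beta, rel=0.01)

    def test_estimators_agree_for_light_damping(self):
        ring = dyn.extract_ringdown(self._damped_cosine(8e8, 1e7))
        assert ring.omega_periodogram == pytest.approx(ring.omega_damped, rel=0.02)

    def test_constant_trajectory_rejected(self):
        t = np.linspace(0.0, 1e-7, 100)
        traj = dyn.RadialTrajectory(t=t, R=np.full_like(t, 1e-5), Rdot=np.zeros_like(t))
        with pytest.raises(NoOscillationError):
            dyn.extract_ringdown(traj, R_ref=1e-5)


class TestMediumValidation:
    def test_vapor_pressure_must_be_below_static(self):
        with pytest.raises(DomainError):
            dyn.MediumProperties(P0=1e4, P_v=2e4)

    def test_from_config_with_unit_suffixes(self):
        m = dyn.MediumProperties.from_config(
            {"P0": "101 kPa", "P_v": "2.34 kPa", "temperature_K": 293.15}
        )
        assert m.P0 == pytest.approx(1.01e6)
        assert m.P_v == pytest.approx(2.34e4)

    def test_from_config_rejects_unknown_keys(self):
        with pytest.raises(DomainError):
            dyn.MediumProperties.from_config({"viscocity": 1.0})
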