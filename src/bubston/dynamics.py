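"""Radial oscillations of a charged gas bubble (charged Rayleigh-Plesset).

The radius R(t) of a spherical, charged gas bubble in a weakly compressible
viscous liquid under an acoustic drive ``P_s sin(omega t)`` obeys

    [ (1 - Rdot/c_s) R + 4 eta / (c_s rho) ] Rddot =
          (1/rho) (P0 - P_v + 2 Gamma/R0 - Q^2/(8 pi eps R0^4))
              * (R0/R)^(3 gamma) * (1 + (1 - 3 gamma) Rdot/c_s)
        - (Rdot^2 / 2) (3 - Rdot/c_s)
        + Q^2 / (8 pi eps rho R^4) * (1 - 3 Rdot/c_s)
        - 2 Gamma / (rho R)  -  4 eta Rdot / (rho R)
        - (1/rho) (P0 - P_v + P_s sin(omega t)) (1 + Rdot/c_s)
        - (R / (rho c_s)) P_s omega cos(omega t)

where R0 is the equilibrium radius (an exact rest state of the equation),
gamma the adiabatic index of the gas, and Q the charge carried by the bubble
surface.  Bracket placement notes (each resolved so that R = R0, Rdot = 0 is
an exact equilibrium and the linearization reproduces the closed-form
eigenfrequency below):

* the compressibility factor ``(1 + (1 - 3 gamma) Rdot/c_s)`` multiplies the
  polytropic gas term only;
* ``(1 + Rdot/c_s)`` multiplies the combined far-field pressure
  ``P0 - P_v + P_s sin(omega t)`` (Keller-Miksis convention);
* the quadratic velocity term is the standard ``(3/2) Rdot^2 (1 - Rdot/3c_s)``.

Linearizing about R0 (with gamma = 5/3, so 3 gamma = 5) gives the natural
angular frequency

    omega_0^2 = [5 (P0 - P_v) + 8 Gamma/R0 - Q^2/(8 pi eps R0^4)]
                / [rho R0^2 (1 + 4 eta / (c_s rho R0))]

implemented in :func:`natural_frequency`, and an attenuation coefficient

    beta = [4 (P0 - P_v) + 8 Gamma/R0 + 4 eta c_s / R0 - Q^2/(8 pi eps R0^4)]
           / [rho c_s R0 (1 + 4 eta / (c_s rho R0))]

implemented in :func:`damping_coefficient`.  Note that this attenuation
expression is numerically ~2x the amplitude decay rate of the linearized
equation (it tracks energy rather than amplitude decay); the ring-down
extractor reports fitted rates so the two can be compared directly.

Internally the integrator works in nanoseconds and in units of R0 for
conditioning (natural frequencies are ~1e9 s^-1 on ~1e-5 cm bubbles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import periodogram

from .errors import (
    BubbleCollapseError,
    DomainError,
    NoOscillationError,
    NoRealEigenfrequencyError,
    SolverError,
)
from .units import SPEED_OF_LIGHT, energy_from_kelvin, parse_quantity


@dataclass(frozen=True)
class MediumProperties:
    """Bulk liquid/gas parameters, CGS-Gaussian.  Defaults: air-saturated water at 20 C.

    ``T`` is temperature in energy units (erg).
    """

    rho_l: float = 1.0               # liquid density, g/cm^3
    rho_g: float = 1e-3              # gas density, g/cm^3
    eta: float = 0.01                # dynamic viscosity, poise
    c_s: float = 1.48e5              # sound speed in the liquid, cm/s
    epsilon: float = 82.0            # relative permittivity
    gamma_surface: float = 73.0      # surface tension, dyn/cm
    P0: float = 1.01e6               # static (atmospheric) pressure, dyn/cm^2
    P_v: float = 2.34e4              # vapor pressure, dyn/cm^2
    gamma_adiabatic: float = 5.0 / 3.0
    T: float = energy_from_kelvin(293.15)

    def __post_init__(self):
        positive = {
            "rho_l": self.rho_l, "rho_g": self.rho_g, "eta": self.eta,
            "c_s": self.c_s, "epsilon": self.epsilon,
            "gamma_surface": self.gamma_surface, "P0": self.P0,
            "P_v": self.P_v, "T": self.T,
        }
        for name, value in positive.items():
            if not (value > 0 and math.isfinite(value)):
                raise DomainError(f"{name} must be positive and finite, got {value}")
        if self.P0 <= self.P_v:
            raise DomainError("static pressure must exceed vapor pressure")
        if self.gamma_adiabatic <= 1:
            raise DomainError("adiabatic index must exceed 1")

    @property
    def c_em(self) -> float:
        """Phase speed of electromagnetic waves in the medium, ``c0 / sqrt(eps)``."""
        return SPEED_OF_LIGHT / math.sqrt(self.epsilon)

    @classmethod
    def from_config(cls, cfg: dict) -> "MediumProperties":
        """Build from a config mapping with explicit unit suffixes.

        Example entry: ``{"P0": "101 kPa", "temperature_K": 293.15, ...}``.
        Unknown keys are rejected.
        """
        dims = {
            "P0": "pressure", "P_v": "pressure",
            "gamma_surface": None, "eta": None, "rho_l": None, "rho_g": None,
            "c_s": None, "epsilon": None, "gamma_adiabatic": None,
        }
        kwargs = {}
        for key, raw in cfg.items():
            if key == "temperature_K":
                kwargs["T"] = energy_from_kelvin(float(raw))
            elif key in ("P0", "P_v"):
                kwargs[key] = parse_quantity(raw, "pressure") if isinstance(raw, str) else float(raw)
            elif key in dims:
                kwargs[key] = float(raw)
            else:
                raise DomainError(f"unknown medium parameter {key!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class AcousticDrive:
    """Periodic pressure drive ``P_s sin(omega t)``; ``P_s = 0`` means no drive."""

    P_s: float = 0.0      # amplitude, dyn/cm^2
    omega: float = 0.0    # angular frequency, s^-1

    def __post_init__(self):
        if self.P_s < 0 or self.omega < 0:
            raise DomainError("drive amplitude and frequency must be non-negative")


@dataclass(frozen=True)
class RadialTrajectory:
    """Time series of the bubble radius from the radial integration."""

    t: np.ndarray        # s, strictly increasing
    R: np.ndarray        # cm, > 0
    Rdot: np.ndarray     # cm/s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("time grid must be strictly increasing")
        if np.any(self.R <= 0):
            raise DomainError("radius must stay positive")


def _stiffness_sum(medium: MediumProperties, R0: float, Q: float) -> float:
    """5(P0-Pv) + 8 Gamma/R0 - Q^2/(8 pi eps R0^4)  (dyn/cm^2)."""
    return (
        5.0 * (medium.P0 - medium.P_v)
        + 8.0 * medium.gamma_surface / R0
        - Q**2 / (8.0 * math.pi * medium.epsilon * R0**4)
    )


def _viscous_factor(medium: MediumProperties, R0: float) -> float:
    return 1.0 + 4.0 * medium.eta / (medium.c_s * medium.rho_l * R0)


def natural_frequency(medium: MediumProperties, R0: float, Q: float) -> float:
    """Closed-form natural angular frequency omega_0 (s^-1) of radial oscillation.

    Raises :class:`NoRealEigenfrequencyError` (carrying omega_0^2) when the
    charge term overwhelms the restoring terms.
    """
    if R0 <= 0:
        raise DomainError(f"R0 must be positive, got {R0}")
    w2 = _stiffness_sum(medium, R0, Q) / (
        medium.rho_l * R0**2 * _viscous_factor(medium, R0)
    )
    if w2 <= 0:
        raise NoRealEigenfrequencyError(w2)
    return math.sqrt(w2)


class Damping(NamedTuple):
    beta: float   # attenuation coefficient, s^-1
    tau: float    # decay time 1/beta, s


def damping_coefficient(medium: MediumProperties, R0: float, Q: float) -> Damping:
    """Closed-form attenuation coefficient beta (s^-1) and decay time 1/beta.

    This expression tracks the energy decay of the linearized oscillator (it
    is ~2x the amplitude decay rate); see the module docstring.
    """
    if R0 <= 0:
        raise DomainError(f"R0 must be positive, got {R0}")
    num = (
        4.0 * (medium.P0 - medium.P_v)
        + 8.0 * medium.gamma_surface / R0
        + 4.0 * medium.eta * medium.c_s / R0
        - Q**2 / (8.0 * math.pi * medium.epsilon * R0**4)
    )
    beta = num / (medium.rho_l * medium.c_s * R0 * _viscous_factor(medium, R0))
    return Damping(beta=beta, tau=1.0 / beta)


def amplitude_decay_rate(medium: MediumProperties, R0: float, Q: float) -> float:
    """Amplitude decay rate of the linearized radial equation (s^-1).

    Obtained by linearizing the full radial equation about R0:
    ``beta_amp = [S + 4 eta c_s / R0] / (2 rho c_s R0 (1 + 4 eta/(c_s rho R0)))``
    with S the stiffness sum of :func:`natural_frequency`.  Used as the
    independent oracle for ring-down envelope fits.
    """
    if R0 <= 0:
        raise DomainError(f"R0 must be positive, got {R0}")
    S = _stiffness_sum(medium, R0, Q)
    return (S + 4.0 * medium.eta * medium.c_s / R0) / (
        2.0 * medium.rho_l * medium.c_s * R0 * _viscous_factor(medium, R0)
    )


def integrate_radial_dynamics(
    R_init: float,
    Rdot_init: float,
    R0: float,
    Q: float,
    medium: MediumProperties,
    drive: AcousticDrive = AcousticDrive(),
    t_span: tuple[float, float] = (0.0, 1e-7),
    rtol: float = 1e-9,
    atol: float = 1e-13,
    n_samples: int = 4000,
    method: str = "LSODA",
) -> RadialTrajectory:
    """Integrate the charged radial equation; returns a dense trajectory.

    Parameters
    ----------
    R_init, Rdot_init:
        Initial radius (cm) and radial velocity (cm/s).
    R0:
        Equilibrium radius entering the polytropic reference state, cm.
    Q:
        Bubble charge, esu.
    t_span:
        Integration window in seconds.
    rtol, atol:
        Solver tolerances on the dimensionless state (R/R0, velocity in
        R0/ns units).

    Raises
    ------
    BubbleCollapseError
        If the radius falls below 1% of R0 (structured, carries last state).
    SolverError
        On any other integrator failure.
    """
    if R_init <= 0 or R0 <= 0:
        raise DomainError("radii must be positive")
    for name, v in (("R_init", R_init), ("Rdot_init", Rdot_init), ("Q", Q)):
        if not math.isfinite(v):
            raise DomainError(f"{name} must be finite, got {v}")
    if rtol <= 0 or atol <= 0:
        raise DomainError("tolerances must be positive")

    rho, eta, cs = medium.rho_l, medium.eta, medium.c_s
    G, eps = medium.gamma_surface, medium.epsilon
    P0, Pv = medium.P0, medium.P_v
    g3 = 3.0 * medium.gamma_adiabatic
    qterm0 = Q**2 / (8.0 * math.pi * eps * R0**4)
    p_star = P0 - Pv + 2.0 * G / R0 - qterm0
    Ps, om = drive.P_s, drive.omega

    NS = 1e-9  # one nanosecond, s

    # state y = [x, v]; R = x*R0 (cm), Rdot = v*R0/NS (cm/s); time u in ns
    def rhs(u, y):
        x, v = y
        R = x * R0
        Rdot = v * R0 / NS
        t = u * NS
        qterm = Q**2 / (8.0 * math.pi * eps * R**4)
        f = (
            (p_star / rho) * (R0 / R) ** g3 * (1.0 + (1.0 - g3) * Rdot / cs)
            - 0.5 * Rdot**2 * (3.0 - Rdot / cs)
            + (qterm / rho) * (1.0 - 3.0 * Rdot / cs)
            - 2.0 * G / (rho * R)
            - 4.0 * eta * Rdot / (rho * R)
            - (P0 - Pv + Ps * math.sin(om * t)) * (1.0 + Rdot / cs) / rho
            - (R / (rho * cs)) * Ps * om * math.cos(om * t)
        )
        denom = (1.0 - Rdot / cs) * R + 4.0 * eta / (cs * rho)
        Rddot = f / denom  # cm/s^2
        return [Rdot * NS / R0, Rddot * NS**2 / R0]

    def collapse(u, y):
        return y[0] - 0.01

    collapse.terminal = True
    collapse.direction = -1

    u_span = (t_span[0] / NS, t_span[1] / NS)
    u_eval = np.linspace(u_span[0], u_span[1], n_samples)
    sol = solve_ivp(
        rhs,
        u_span,
        [R_init / R0, Rdot_init * NS / R0],
        t_eval=u_eval,
        rtol=rtol,
        atol=atol,
        method=method,
        events=[collapse],
        dense_output=False,
    )
    if sol.t.size:
        last = (
            float(sol.t[-1] * NS),
            float(sol.y[0][-1] * R0),
            float(sol.y[1][-1] * R0 / NS),
        )
    else:
        last = (t_span[0], R_init, Rdot_init)
    if sol.status == 1:  # collapse event fired
        raise BubbleCollapseError(last)
    if not sol.success:
        raise SolverError(last, sol.message)

    return RadialTrajectory(
        t=sol.t * NS,
        R=sol.y[0] * R0,
        Rdot=sol.y[1] * R0 / NS,
        metadata={
            "R0_cm": R0,
            "Q_esu": Q,
            "drive_Ps": Ps,
            "drive_omega": om,
            "rtol": rtol,
            "atol": atol,
            "method": method,
        },
    )


@dataclass(frozen=True)
class RingdownResult:
    """Frequency/decay extracted from a free-decay trajectory.

    ``omega_damped`` comes from zero-crossing intervals, cross-checked by
    ``omega_periodogram`` (spectral peak with parabolic interpolation).
    ``beta`` is the amplitude decay rate from a log-envelope linear fit.
    ``omega_natural = sqrt(omega_damped^2 + beta^2)`` is the undamped natural
    frequency implied by the damped oscillation (standard modal-analysis
    correction; equals the closed-form eigenfrequency in the linear regime).
    """

    omega_damped: float
    omega_damped_err: float
    omega_periodogram: float
    beta: float
    beta_err: float

    @property
    def omega_natural(self) -> float:
        return math.hypot(self.omega_damped, self.beta)


def extract_ringdown(traj: RadialTrajectory, R_ref: float | None = None) -> RingdownResult:
    """Extract (angular frequency, decay rate) from a free ring-down.

    ``R_ref`` defaults to the trajectory's recorded equilibrium radius (or the
    mean of the final 10% of samples).  Only the portion of the signal whose
    envelope exceeds 1e-3 of the peak deviation is used, so the integrator's
    noise floor does not pollute the fits.

    Raises :class:`NoOscillationError` when fewer than six usable
    zero-crossings (three periods) are present.
    """
    if R_ref is None:
        R_ref = traj.metadata.get("R0_cm") or float(np.mean(traj.R[-len(traj.R) // 10 :]))
    x = traj.R - R_ref
    t = traj.t
    peak = float(np.max(np.abs(x)))
    if peak <= 0 or peak < 1e-12 * R_ref:
        raise NoOscillationError("trajectory is constant to solver precision")

    # zero crossings by linear interpolation
    s = np.sign(x)
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    crossings = t[idx] - x[idx] * (t[idx + 1] - t[idx]) / (x[idx + 1] - x[idx])

    # local extrema (envelope samples)
    d = np.diff(x)
    ext = np.nonzero(d[:-1] * d[1:] < 0)[0] + 1
    amp = np.abs(x[ext])
    keep = amp > 1e-3 * peak
    ext, amp = ext[keep], amp[keep]
    if crossings.size >= 2:
        t_last = crossings[-1] if ext.size == 0 else max(crossings[-1], t[ext[-1]])
    else:
        t_last = t[-1]
    crossings = crossings[crossings <= t_last + (t[1] - t[0])]

    if crossings.size < 6 or ext.size < 3:
        raise NoOscillationError(
            f"insufficient oscillatory content ({crossings.size} crossings)"
        )

    half_periods = np.diff(crossings)
    omega_zc = math.pi / float(np.mean(half_periods))
    omega_zc_err = (
        math.pi * float(np.std(half_periods, ddof=1))
        / (float(np.mean(half_periods)) ** 2 * math.sqrt(half_periods.size))
    )

    # periodogram cross-check with parabolic peak interpolation
    freqs, power = periodogram(x, fs=1.0 / float(t[1] - t[0]), window="hann")
    k = int(np.argmax(power[1:]) + 1)
    if 0 < k < len(power) - 1:
        y0, y1, y2 = power[k - 1], power[k], power[k + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    else:
        shift = 0.0
    f_peak = (k + shift) * (freqs[1] - freqs[0])
    omega_fft = 2.0 * math.pi * f_peak

    # log-envelope linear fit for the amplitude decay rate
    coeffs, cov = np.polyfit(t[ext], np.log(amp), 1, cov=True)
    beta_fit = -float(coeffs[0])
    beta_err = float(math.sqrt(cov[0, 0]))

    return RingdownResult(
        omega_damped=omega_zc,
        omega_damped_err=omega_zc_err,
        omega_periodogram=omega_fft,
        beta=beta_fit,
        beta_err=beta_err,
    )
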