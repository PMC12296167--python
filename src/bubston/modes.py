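"""Legendre shape modes of a charged bubble and their electromagnetic emission.

Small deformations of the compound species' surface are expanded in Legendre
polynomials,

    xi(theta, t) = sum_{n>=2} alpha_n P_n(cos theta) exp(-i omega_n t),

(n = 0 is the volume mode handled by the radial dynamics, n = 1 a pure
translation; neither deforms the sphere).  The mode frequencies of a charged
sphere of radius R in a liquid of density rho_l with interior gas density
rho_g are

    omega_n0^2 = n (n+1) (n-1) / (rho_l n + rho_g (n+1))
                 * [ Gamma (n+2) / R^3 - Q^2 / (4 pi eps_l R^6) ]      ("full")

whose charge term softens the mode toward the Rayleigh fission threshold
(Q^2 = 16 pi Gamma R^3 at n = 2, up to the medium permittivity), and, with the
charge a negligible perturbation and the gas inertia dropped,

    omega_n0^2 = Gamma (n+1)(n-1)(n+2) / (rho_l R^3)                ("uncharged")

A mode of amplitude ratio beta_n = dR/R0 radiates an electromagnetic wave of
multipole order n through the oscillation of its shell charge Q; the radiated
intensity of a single species is

    I = Q^2 Gamma^(n+1) beta_n^2 / (4 eps(omega_n0) c^(2n+1) R^(n+5))
        * (n-1) (n+1)^2 (2n+1)^2 n^(n+1)
          / [ ((2n-1)!!)^2 (n+2)^n (n rho_l + (n+1) rho_g)^(n+1) ]

with c = c0/sqrt(eps) the wave speed in the liquid and (2n-1)!! the double
factorial familiar from multipole radiation; the density-weighted factor is
the same two-fluid inertial combination that appears in the mode frequency.
Computed in CGS (erg s^-1 cm^-2) and reported in W/m^2.  The n = 2 baseline
scales as Q^2 / R^7: halving the radius at constant surface-charge density
(Q -> Q/4) multiplies the intensity by exactly 2^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

from .dynamics import MediumProperties
from .errors import DomainError, NoRealEigenfrequencyError
from .units import SPEED_OF_LIGHT


def double_factorial_odd(n: int) -> int:
    """(2n - 1)!! for n >= 1; equals 3 at n = 2."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    out = 1
    for k in range(3, 2 * n, 2):
        out *= k
    return out


@dataclass(frozen=True)
class InstabilityDiagnostic:
    """Rayleigh fission diagnostic of a charged sphere.

    ``parameter = Q^2 / (16 pi Gamma R^3)``; the surface is unstable (fission,
    sustained shape oscillation) at ``parameter >= 1``.  ``ridge_height`` is
    the thermal capillary ridge scale ``sqrt(T / Gamma)`` seeding the modes.
    """

    parameter: float
    critical_charge: float
    ridge_height: float | None = None

    @property
    def unstable(self) -> bool:
        return self.parameter >= 1.0


def rayleigh_parameter(
    Q: float, gamma: float, R: float, T: float | None = None
) -> InstabilityDiagnostic:
    """Dimensionless Rayleigh instability parameter ``Q^2 / (16 pi Gamma R^3)``."""
    if R <= 0 or gamma <= 0:
        raise DomainError("R and Gamma must be positive")
    crit = math.sqrt(16.0 * math.pi * gamma * R**3)
    ridge = None if T is None else math.sqrt(T / gamma)
    return InstabilityDiagnostic(
        parameter=Q**2 / crit**2, critical_charge=crit, ridge_height=ridge
    )


@dataclass(frozen=True)
class ShapeMode:
    """One Legendre mode: index n >= 2, (possibly complex) angular frequency, amplitude."""

    n: int
    omega: complex
    alpha: float = 0.0

    def __post_init__(self):
        if self.n < 2:
            raise DomainError(
                f"shape modes require n >= 2 (n=0 is radial, n=1 translation), got {self.n}"
            )


@dataclass(frozen=True)
class ModeSpectrum:
    """Collection of shape modes of one species, with its physical parameters."""

    modes: tuple[ShapeMode, ...]
    Q: float = 0.0
    R: float = 0.0
    beta_n: float = 0.01

    def __post_init__(self):
        if not self.modes:
            raise DomainError("mode spectrum must contain at least one mode")


def surface_perturbation(theta, t: float, modes: ModeSpectrum):
    """Real surface displacement xi(theta, t) summed over the spectrum (cm).

    ``omega`` may carry a negative imaginary part encoding decay; the real
    part of ``alpha_n P_n(cos theta) exp(-i omega_n t)`` is summed.
    Accepts scalar or array ``theta``.
    """
    theta = np.asarray(theta, dtype=float)
    xi = np.zeros_like(theta)
    for m in modes.modes:
        phase = np.exp(-1j * m.omega * t)
        xi = xi + m.alpha * eval_legendre(m.n, np.cos(theta)) * phase.real
    return xi if xi.shape else float(xi)


def mode_frequency(
    n: int,
    Q: float,
    R: float,
    medium: MediumProperties,
    variant: str = "full",
) -> float:
    """Natural angular frequency omega_n0 (s^-1) of shape mode n.

    ``variant="full"`` includes the charge softening and the two-fluid
    inertial denominator; ``variant="uncharged"`` is the light-gas,
    zero-charge capillary limit.  ``n = 1`` returns 0 in the uncharged
    variant (translation).  A charge-dominated negative omega^2 raises
    :class:`NoRealEigenfrequencyError` carrying the squared value.
    """
    if n < 1:
        raise DomainError(f"mode index must be >= 1, got {n}")
    if R <= 0:
        raise DomainError(f"R must be positive, got {R}")
    G, rho_l, rho_g = medium.gamma_surface, medium.rho_l, medium.rho_g
    if variant == "uncharged":
        w2 = G * (n + 1) * (n - 1) * (n + 2) / (rho_l * R**3)
    elif variant == "full":
        stiff = G * (n + 2) / R**3 - Q**2 / (4.0 * math.pi * medium.epsilon * R**6)
        w2 = n * (n + 1) * (n - 1) / (rho_l * n + rho_g * (n + 1)) * stiff
    else:
        raise DomainError(f"unknown variant {variant!r}")
    if w2 < 0:
        raise NoRealEigenfrequencyError(w2)
    return math.sqrt(w2)


def species_intensity(
    n: int,
    Q: float,
    R: float,
    beta_n: float,
    medium: MediumProperties,
    omega_n0: float,
) -> float:
    """Radiated intensity (W/m^2) of a single species oscillating in mode n.

    ``omega_n0`` is a free argument rather than being recomputed from
    :func:`mode_frequency`: it enters the emission only through the
    permittivity dispersion ``eps(omega_n0)`` (taken from ``medium.epsilon``,
    constant over the GHz band modelled here), and keeping it explicit lets a
    caller evaluate the emission at any assumed oscillation frequency.
    The reported number is the formula value on the same flux scale used for
    the radiometric comparisons.
    """
    if n < 2:
        raise DomainError(f"radiating shape modes require n >= 2, got {n}")
    if not 0.0 < beta_n < 1.0:
        raise DomainError(f"beta_n must be in (0, 1), got {beta_n}")
    if omega_n0 <= 0:
        raise DomainError(f"omega_n0 must be positive, got {omega_n0}")
    if R <= 0:
        raise DomainError(f"R must be positive, got {R}")
    eps = medium.epsilon
    c = SPEED_OF_LIGHT / math.sqrt(eps)
    G, rho_l, rho_g = medium.gamma_surface, medium.rho_l, medium.rho_g
    dfact = double_factorial_odd(n)
    numeric = (
        (n - 1) * (n + 1) ** 2 * (2 * n + 1) ** 2 * n ** (n + 1)
    ) / (
        dfact**2 * (n + 2) ** n * (n * rho_l + (n + 1) * rho_g) ** (n + 1)
    )
    I_cgs = (
        Q**2 * G ** (n + 1) * beta_n**2
        / (4.0 * eps * c ** (2 * n + 1) * R ** (n + 5))
        * numeric
    )
    return I_cgs * 1e-3  # erg s^-1 cm^-2 -> W/m^2


@dataclass(frozen=True)
class HalfRadiusScaling:
    """Result of the constant-surface-charge-density half-radius rescaling."""

    intensity: float
    factor: float = 8.0


def intensity_scaling_half_radius(I_base: float) -> HalfRadiusScaling:
    """Intensity after halving R at constant surface-charge density.

    Q scales with surface area (Q -> Q/4), so Q^2/R^7 -> (Q^2/16)/(R^7/128),
    i.e. the n = 2 intensity grows by exactly 2^3 = 8.
    """
    if I_base <= 0:
        raise DomainError(f"I_base must be positive, got {I_base}")
    return HalfRadiusScaling(intensity=8.0 * I_base, factor=8.0)


def coherent_intensity(I_single: float, k: int) -> float:
    """Intensity of k identical in-phase oscillators: amplitudes add, so k^2 I."""
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise DomainError(f"k must be an integer >= 1, got {k!r}")
    if I_single < 0:
        raise DomainError(f"I_single must be non-negative, got {I_single}")
    return k**2 * I_single


def mode_spectrum_table(
    Q: float,
    R: float,
    medium: MediumProperties,
    beta_n: float = 0.01,
    n_max: int = 6,
) -> list[dict]:
    """Tabulate frequencies (both variants), intensities and the instability
    diagnostic for modes n = 2..n_max.  Used by the CLI ``modes`` subcommand."""
    diag = rayleigh_parameter(Q, medium.gamma_surface, R, T=medium.T)
    rows = []
    for n in range(2, n_max + 1):
        w_full = mode_frequency(n, Q, R, medium, "full")
        w_unch = mode_frequency(n, Q, R, medium, "uncharged")
        rows.append(
            {
                "n": n,
                "omega_full_per_s": w_full,
                "omega_uncharged_per_s": w_unch,
                "intensity_W_m2": species_intensity(n, Q, R, beta_n, medium, w_full),
                "rayleigh_parameter": diag.parameter,
            }
        )
    return rows
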