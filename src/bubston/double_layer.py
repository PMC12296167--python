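"""Electrostatics of the screening layer around a charged nanobubble.

The gas core of radius ``R_b`` carries a shell charge ``Q`` (anions embedded
in its boundary layer).  In a 1:1 electrolyte of bulk density ``n_is`` the
mobile counterion cloud is described here in the Debye-Hueckel (linearized
Poisson-Boltzmann) approximation, which gives closed forms for the potential
and charge-density profiles outside the shell:

    phi(r) = Q exp(-kappa (r - R_b)) / (eps (1 + kappa R_b) r)
    rho(r) = -kappa^2 Q exp(-kappa (r - R_b)) / (4 pi (1 + kappa R_b) r)

with kappa^2 = 8 pi l_B n_is and the Bjerrum length l_B = e^2/(eps T).
The diffuse cloud integrates to exactly -Q (screening neutrality), which the
test-suite checks by quadrature.  The dense (Stern) part of the double layer
is represented only by thickness bookkeeping (``stern_thickness``); the field
solution applies outward of the shell.

All quantities are CGS-Gaussian; temperatures are in energy units (erg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UsageError
from .units import ELEMENTARY_CHARGE


def bjerrum_length(epsilon: float, T: float) -> float:
    """Bjerrum length ``e^2 / (epsilon T)`` in cm.

    Distance at which the Coulomb energy of two elementary charges in the
    medium equals the thermal energy ``T`` (erg).
    """
    if epsilon <= 0 or T <= 0:
        raise DomainError(f"epsilon and T must be positive, got {epsilon}, {T}")
    return ELEMENTARY_CHARGE**2 / (epsilon * T)


@dataclass(frozen=True)
class IonBackground:
    """Bulk 1:1 electrolyte far from any bubble surface.

    Attributes
    ----------
    n_is:
        Bulk ion number density of each species, cm^-3.
    l_B:
        Bjerrum length of the medium, cm.
    kappa:
        Inverse Debye screening length ``sqrt(8 pi l_B n_is)``, cm^-1.
    """

    n_is: float
    l_B: float
    kappa: float

    @property
    def debye_length(self) -> float:
        if self.kappa == 0.0:
            return math.inf
        return 1.0 / self.kappa


def debye_kappa(n_is: float, l_B: float) -> IonBackground:
    """Inverse Debye length of a 1:1 electrolyte; ``kappa = 0`` iff ``n_is = 0``."""
    if n_is < 0:
        raise DomainError(f"ion density must be non-negative, got {n_is}")
    if l_B <= 0:
        raise DomainError(f"Bjerrum length must be positive, got {l_B}")
    kappa = math.sqrt(8.0 * math.pi * l_B * n_is)
    return IonBackground(n_is=n_is, l_B=l_B, kappa=kappa)


@dataclass(frozen=True)
class CompoundSpecies:
    """Bubble plus its immobile ion shells, bounded by the slipping surface.

    ``a_c`` is the hydrodynamic (slipping-surface) radius and ``Q_c`` the net
    charge inside it; the electrokinetic potential at that surface is
    ``zeta = Q_c / (eps a_c)`` exactly.
    """

    a_c: float
    Q_c: float
    zeta: float
    epsilon: float

    @property
    def charge_in_elementary(self) -> float:
        return self.Q_c / ELEMENTARY_CHARGE


def zeta_charge_relation(
    a_c: float,
    epsilon: float,
    zeta: float | None = None,
    Q_c: float | None = None,
) -> CompoundSpecies:
    """Fill in the missing one of (zeta, Q_c) from ``zeta = Q_c/(eps a_c)``.

    Exactly one of ``zeta`` (statvolt) / ``Q_c`` (esu) must be supplied.
    """
    if a_c <= 0:
        raise DomainError(f"hydrodynamic radius must be positive, got {a_c}")
    if epsilon <= 0:
        raise DomainError(f"permittivity must be positive, got {epsilon}")
    if (zeta is None) == (Q_c is None):
        raise UsageError("supply exactly one of zeta or Q_c")
    if zeta is None:
        zeta = Q_c / (epsilon * a_c)
    else:
        Q_c = zeta * epsilon * a_c
    return CompoundSpecies(a_c=a_c, Q_c=Q_c, zeta=zeta, epsilon=epsilon)


def mean_spacing(n_b: float) -> float:
    """Mean inter-particle distance ``n_b^(-1/3)`` (cm) at number density n_b."""
    if n_b <= 0:
        raise DomainError(f"number density must be positive, got {n_b}")
    return n_b ** (-1.0 / 3.0)


def stern_thickness(a_c: float, R_b: float) -> float:
    """Thickness of the dense counterion layer, ``a_c - R_b`` (cm)."""
    if a_c < R_b:
        raise DomainError(
            f"slipping surface (a_c={a_c}) cannot lie inside the gas core (R_b={R_b})"
        )
    return a_c - R_b


@dataclass(frozen=True)
class DoubleLayerProfile:
    """Radial profiles of the diffuse double layer outside the charged shell.

    Arrays are evaluated on the supplied grid ``r >= R_b``.  ``n_cation`` /
    ``n_anion`` follow the Boltzmann weights exp(-e phi/T) / exp(+e phi/T);
    ``rho`` is the linearized (Debye-Hueckel) charge density, whose sign is
    everywhere opposite to the shell charge.  ``linearization`` is the
    diagnostic ``e |phi(R_b)| / T`` — the closed forms assume it is << 1; it
    is reported, never enforced.
    """

    r: np.ndarray
    phi: np.ndarray
    rho: np.ndarray
    n_cation: np.ndarray
    n_anion: np.ndarray
    Q: float
    R_b: float
    epsilon: float
    kappa: float
    n_is: float
    linearization: float

    @property
    def phi_surface(self) -> float:
        """phi(R_b) = Q / (eps R_b (1 + kappa R_b))."""
        return self.Q / (self.epsilon * self.R_b * (1.0 + self.kappa * self.R_b))

    def integrated_charge(self, r: float) -> float:
        """Closed-form diffuse charge inside radius ``r``: int rho 4 pi x^2 dx.

        Tends to ``-Q`` as r -> inf (complete screening of the shell).
        """
        if r < self.R_b:
            raise DomainError("r must be >= R_b")
        k = self.kappa
        if k == 0.0:
            return 0.0
        u = math.exp(-k * (r - self.R_b)) * (1.0 + k * r)
        return -self.Q * (1.0 - u / (1.0 + k * self.R_b))

    def summary(self) -> dict:
        return {
            "Q_esu": self.Q,
            "R_b_cm": self.R_b,
            "epsilon": self.epsilon,
            "kappa_per_cm": self.kappa,
            "debye_length_cm": math.inf if self.kappa == 0 else 1.0 / self.kappa,
            "phi_surface_statvolt": self.phi_surface,
            "integrated_charge_esu": self.integrated_charge(float(self.r[-1])),
            "linearization_e_phi_over_T": self.linearization,
        }


def build_profile(
    Q: float,
    R_b: float,
    background: IonBackground,
    epsilon: float,
    r_grid: np.ndarray,
    T: float,
) -> DoubleLayerProfile:
    """Evaluate the Debye-Hueckel double-layer profiles on ``r_grid``.

    Parameters
    ----------
    Q:
        Shell charge, esu (negative for anion-stabilized bubbles).
    R_b:
        Gas-core (shell) radius, cm.
    background:
        Bulk electrolyte (1:1 only; built by :func:`debye_kappa`).
    epsilon:
        Relative permittivity of the liquid.
    r_grid:
        Radii, cm, all >= R_b.
    T:
        Temperature in energy units (erg), used for the ion Boltzmann
        factors and the linearization diagnostic.
    """
    if R_b <= 0:
        raise DomainError(f"R_b must be positive, got {R_b}")
    if epsilon <= 0 or T <= 0:
        raise DomainError("epsilon and T must be positive")
    if background.kappa < 0:
        raise DomainError("kappa must be non-negative")
    r = np.asarray(r_grid, dtype=float)
    if np.any(r < R_b):
        raise DomainError("all grid radii must satisfy r >= R_b")

    k = background.kappa
    damp = np.exp(-k * (r - R_b))
    phi = Q * damp / (epsilon * (1.0 + k * R_b) * r)
    rho = -(k**2) * Q * damp / (4.0 * math.pi * (1.0 + k * R_b) * r)

    x = ELEMENTARY_CHARGE * phi / T
    n_cation = background.n_is * np.exp(-x)
    n_anion = background.n_is * np.exp(+x)

    phi_s = Q / (epsilon * R_b * (1.0 + k * R_b))
    diag = abs(ELEMENTARY_CHARGE * phi_s / T)

    return DoubleLayerProfile(
        r=r,
        phi=phi,
        rho=rho,
        n_cation=n_cation,
        n_anion=n_anion,
        Q=Q,
        R_b=R_b,
        epsilon=epsilon,
        kappa=k,
        n_is=background.n_is,
        linearization=diag,
    )
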