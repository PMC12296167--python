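"""Mechanical and diffusional equilibrium of an ion-stabilized bubble.

A small gas bubble is squeezed by surface tension (Laplace pressure
``2 Gamma / R_b``) and stretched by the outward ponderomotive (Maxwell-stress)
pressure of the charge embedded in its boundary layer,
``P_e = Q0^2 / (8 pi eps R_b^4)``.  When the two balance, the internal gas
pressure equals the ambient one, the bubble is simultaneously in mechanical
and diffusional equilibrium, and its radius is

    R_b = [ Q0^2 / (16 pi eps Gamma) ]^(1/3).

All quantities CGS-Gaussian.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import DomainError
from .units import GAS_SOLUBILITY_DEFAULT, LOSCHMIDT_NUMBER


@dataclass(frozen=True)
class BubstonState:
    """Gas-core radius and shell charge of an ion-stabilized bubble.

    ``residual`` records how far the state is from the joint equilibrium
    condition (zero for states built by :func:`equilibrium_radius`).
    """

    R_b: float
    Q0: float
    gamma_surface: float
    epsilon: float
    residual: float = 0.0

    def __post_init__(self):
        if self.R_b < 0:
            raise DomainError(f"R_b must be non-negative, got {self.R_b}")
        if self.gamma_surface <= 0:
            raise DomainError(f"surface tension must be positive, got {self.gamma_surface}")
        if self.epsilon <= 0:
            raise DomainError(f"permittivity must be positive, got {self.epsilon}")


def laplace_internal_pressure(P0: float, gamma: float, R_b: float) -> float:
    """Internal gas pressure of an uncharged bubble: ``P0 + 2 gamma / R_b``."""
    if R_b <= 0:
        raise DomainError(f"R_b must be positive, got {R_b}")
    return P0 + 2.0 * gamma / R_b


def electrostatic_free_energy(Q0: float, R_b: float, r: float, epsilon: float) -> float:
    """Electrostatic free energy of the shell charge's field between R_b and r.

    ``Phi_e(r) = (Q0^2 / 2 eps) (1/R_b - 1/r)``; the r -> inf limit is the
    self-energy ``Q0^2 / (2 eps R_b)`` of a charged shell in the dielectric.
    ``r`` may be ``math.inf``.
    """
    if R_b <= 0:
        raise DomainError(f"R_b must be positive, got {R_b}")
    if r < R_b:
        raise DomainError(f"r={r} must be >= R_b={R_b}")
    inv_r = 0.0 if math.isinf(r) else 1.0 / r
    return Q0**2 / (2.0 * epsilon) * (1.0 / R_b - inv_r)


def ponderomotive_pressure(Q0: float, R_b: float, epsilon: float) -> float:
    """Outward Maxwell-stress pressure on the charged shell.

    ``P_e = Q0^2 / (8 pi eps R_b^4)``, i.e. minus the derivative of
    :func:`electrostatic_free_energy` with respect to the volume of the outer
    spherical layer (closed form; the finite-difference check lives in tests).
    """
    if R_b <= 0:
        raise DomainError(f"R_b must be positive, got {R_b}")
    return Q0**2 / (8.0 * math.pi * epsilon * R_b**4)


def equilibrium_radius(Q0: float, epsilon: float, gamma: float) -> BubstonState:
    """Stable radius where ponderomotive pressure balances surface tension.

    Unique positive root of ``2 gamma / R = Q0^2 / (8 pi eps R^4)``.  A zero
    charge yields the degenerate R_b = 0 (reported with a warning): without
    electrostatic stretching no finite equilibrium exists.
    """
    if gamma <= 0:
        raise DomainError(f"surface tension must be positive, got {gamma}")
    if epsilon <= 0:
        raise DomainError(f"permittivity must be positive, got {epsilon}")
    if Q0 == 0:
        warnings.warn(
            "Q0 = 0: degenerate equilibrium radius R_b = 0 (uncharged bubble "
            "has no stable size)",
            stacklevel=2,
        )
        return BubstonState(R_b=0.0, Q0=0.0, gamma_surface=gamma, epsilon=epsilon)
    R_b = (Q0**2 / (16.0 * math.pi * epsilon * gamma)) ** (1.0 / 3.0)
    res = 2.0 * gamma / R_b - ponderomotive_pressure(Q0, R_b, epsilon)
    return BubstonState(R_b=R_b, Q0=Q0, gamma_surface=gamma, epsilon=epsilon, residual=res)


def equilibrium_residual(state: BubstonState, P0: float, P_in: float) -> float:
    """Pressure imbalance ``(P_in + P_e) - (P0 + 2 Gamma / R_b)``.

    Zero at joint mechanical/diffusional equilibrium with ``P_in = P0``;
    positive when the bubble is over-pressurized (would grow).
    """
    if state.R_b <= 0:
        raise DomainError("residual undefined for degenerate R_b = 0 state")
    P_e = ponderomotive_pressure(state.Q0, state.R_b, state.epsilon)
    return (P_in + P_e) - (P0 + 2.0 * state.gamma_surface / state.R_b)


def dissolved_gas_density(
    N_L: float = LOSCHMIDT_NUMBER, K: float = GAS_SOLUBILITY_DEFAULT
) -> float:
    """Equilibrium number density of dissolved air, ``N_L * K`` (cm^-3)."""
    if N_L <= 0:
        raise DomainError(f"N_L must be positive, got {N_L}")
    if not 0.0 <= K <= 1.0:
        raise DomainError(f"solubility K must be in [0, 1], got {K}")
    return N_L * K
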