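"""Physical constants and unit conversions for the CGS-Gaussian system.

Every model equation in this package is written in CGS-Gaussian (electrostatic)
units: charge in esu (statC), potential in statvolt, pressure in barye
(dyn/cm^2), energy in erg.  SI values are accepted and emitted only at the
I/O boundaries (config parsing, report writing); everything downstream of
:func:`convert` / :func:`parse_quantity` is already CGS.

Temperature is carried internally in *energy units* (erg), i.e. the Boltzmann
constant is folded in: ``T_energy = k_B * T_kelvin``.  Use
:func:`energy_from_kelvin` at the boundary.

Frequencies are treated as angular (s^-1) throughout and reported on that same
scale; "GHz" is accepted as a plain 1e9 s^-1 scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DimensionalityError, DomainError

# ---------------------------------------------------------------------------
# Fundamental constants (CGS-Gaussian)
# ---------------------------------------------------------------------------

#: Elementary charge, esu (statC).
ELEMENTARY_CHARGE = 4.80320425e-10

#: Boltzmann constant, erg/K (exact SI definition scaled to CGS).
BOLTZMANN_CONSTANT = 1.380649e-16

#: Speed of light in vacuum, cm/s.
SPEED_OF_LIGHT = 2.99792458e10

#: Loschmidt number: molecular number density of an ideal gas at standard
#: conditions, cm^-3.
LOSCHMIDT_NUMBER = 2.7e19

#: Dimensionless (Ostwald) solubility of air in water at room conditions.
GAS_SOLUBILITY_DEFAULT = 0.02

#: Default room temperature, K (20 C).
ROOM_TEMPERATURE_K = 293.15

# SI link factors
_ESU_PER_COULOMB = SPEED_OF_LIGHT / 10.0        # 2.99792458e9 esu/C
_VOLT_PER_STATVOLT = 299.792458

# ---------------------------------------------------------------------------
# Conversion table: unit -> (dimension, factor to the CGS base of that dimension)
# ---------------------------------------------------------------------------
# CGS base units per dimension:
#   length: cm | pressure: dyn/cm^2 | potential: statvolt | charge: esu
#   intensity: erg/(s*cm^2) | number_density: cm^-3 | frequency: s^-1
#   energy: erg | volume: cm^3

_UNITS: dict[str, tuple[str, float]] = {
    # length
    "cm": ("length", 1.0),
    "m": ("length", 1e2),
    "mm": ("length", 1e-1),
    "um": ("length", 1e-4),
    "nm": ("length", 1e-7),
    "angstrom": ("length", 1e-8),
    "A": ("length", 1e-8),
    # pressure
    "dyn/cm^2": ("pressure", 1.0),
    "Ba": ("pressure", 1.0),
    "Pa": ("pressure", 10.0),
    "kPa": ("pressure", 1e4),
    "MPa": ("pressure", 1e7),
    "atm": ("pressure", 1.01325e6),
    # electrostatic potential
    "statvolt": ("potential", 1.0),
    "V": ("potential", 1.0 / _VOLT_PER_STATVOLT),
    "mV": ("potential", 1e-3 / _VOLT_PER_STATVOLT),
    # charge
    "esu": ("charge", 1.0),
    "statC": ("charge", 1.0),
    "C": ("charge", _ESU_PER_COULOMB),
    "e": ("charge", ELEMENTARY_CHARGE),
    # radiated intensity (power flux)
    "erg/s/cm^2": ("intensity", 1.0),
    "W/m^2": ("intensity", 1e3),
    # number density
    "cm^-3": ("number_density", 1.0),
    "m^-3": ("number_density", 1e-6),
    # angular frequency
    "s^-1": ("frequency", 1.0),
    "GHz": ("frequency", 1e9),
    "MHz": ("frequency", 1e6),
    # energy
    "erg": ("energy", 1.0),
    "J": ("energy", 1e7),
    # volume
    "cm^3": ("volume", 1.0),
    "mL": ("volume", 1.0),
    "L": ("volume", 1e3),
}


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same dimension.

    Conversion is by fixed multiplicative factors; no rounding is applied.

    Raises
    ------
    DimensionalityError
        If either unit is unknown or the two units measure different
        dimensions.
    """
    try:
        dim_from, f_from = _UNITS[from_unit]
    except KeyError:
        raise DimensionalityError(f"unknown unit {from_unit!r}") from None
    try:
        dim_to, f_to = _UNITS[to_unit]
    except KeyError:
        raise DimensionalityError(f"unknown unit {to_unit!r}") from None
    if dim_from != dim_to:
        raise DimensionalityError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    return value * (f_from / f_to)


def energy_from_kelvin(T_kelvin: float) -> float:
    """Temperature in energy units (erg): ``k_B * T``."""
    if T_kelvin <= 0:
        raise DomainError(f"temperature must be positive, got {T_kelvin} K")
    return BOLTZMANN_CONSTANT * T_kelvin


def kelvin_from_energy(T_energy: float) -> float:
    if T_energy <= 0:
        raise DomainError(f"temperature must be positive, got {T_energy} erg")
    return T_energy / BOLTZMANN_CONSTANT


def parse_quantity(text: str, expect_dimension: str | None = None) -> float:
    """Parse a ``"<number> <unit>"`` string into a CGS base-unit value.

    Used by config loading and the CLI so that every entry carries an explicit
    unit suffix (e.g. ``"101 kPa"`` -> 1.01e6 dyn/cm^2).  ``expect_dimension``
    enables strict validation of the field's dimension.
    """
    parts = text.split()
    if len(parts) != 2:
        raise DimensionalityError(
            f"expected '<number> <unit>', got {text!r}"
        )
    raw, unit = parts
    try:
        value = float(raw)
    except ValueError:
        raise DimensionalityError(f"not a number: {raw!r}") from None
    if unit not in _UNITS:
        raise DimensionalityError(f"unknown unit {unit!r} in {text!r}")
    dim, factor = _UNITS[unit]
    if expect_dimension is not None and dim != expect_dimension:
        raise DimensionalityError(
            f"{text!r} has dimension {dim}, expected {expect_dimension}"
        )
    return value * factor


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of the fundamental constants used throughout the package.

    A single default instance :data:`CGS` is shared; fields mirror the
    module-level constants and exist so that provenance blocks in reports can
    serialize the exact constant set used in a computation.
    """

    elementary_charge: float = ELEMENTARY_CHARGE
    boltzmann_constant: float = BOLTZMANN_CONSTANT
    vacuum_light_speed: float = SPEED_OF_LIGHT
    loschmidt_number: float = LOSCHMIDT_NUMBER
    gas_solubility: float = GAS_SOLUBILITY_DEFAULT
    room_temperature_K: float = ROOM_TEMPERATURE_K

    def as_dict(self) -> dict[str, float]:
        return {
            "elementary_charge_esu": self.elementary_charge,
            "boltzmann_constant_erg_per_K": self.boltzmann_constant,
            "vacuum_light_speed_cm_per_s": self.vacuum_light_speed,
            "loschmidt_number_cm3": self.loschmidt_number,
            "gas_solubility": self.gas_solubility,
            "room_temperature_K": self.room_temperature_K,
        }


CGS = UnitSystem()
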