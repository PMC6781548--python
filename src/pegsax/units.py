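"""Unit handling and the shared constants table.

Internal model units are molar equivalents per kg of film coat
(mol kg^-1): on that scale the stoichiometric bookkeeping of the
degradation network is exact, whereas mass-based units are not (e.g. the
oxidation of formaldehyde to formic acid gains mass). Assay-facing
quantities are expressed in ppm (w/w) against the film coat, the scale
chromatographic impurity results are reported on, and converted at the
I/O boundary.

Supported conversions:

* ``kcal/mol`` <-> ``kJ/mol`` (thermochemical factor 4.184),
* ``ppm_ww`` <-> ``massfrac`` (definition of ppm w/w),
* ``massfrac`` <-> ``molkg`` (requires a species for its molar mass),
* ``ppm_ww`` <-> ``molkg`` (composition of the two above).

Values are converted with exact arithmetic; rounding is applied only by
:func:`display_round` for report formatting (2 decimals, half-even).
"""

from __future__ import annotations

import tomllib
from importlib import resources
from typing import Mapping

__all__ = [
    "CONSTANTS",
    "GAS_CONSTANT",
    "KCAL_TO_KJ",
    "MOLAR_MASS",
    "convert_units",
    "display_round",
]


def _load_constants() -> Mapping:
    with resources.files("pegsax").joinpath("constants.toml").open("rb") as fh:
        return tomllib.load(fh)


CONSTANTS = _load_constants()
GAS_CONSTANT: float = CONSTANTS["physical"]["gas_constant"]
KCAL_TO_KJ: float = CONSTANTS["physical"]["kcal_to_kj"]
#: Molar masses in g/mol, keyed by species symbol.
MOLAR_MASS: dict[str, float] = dict(CONSTANTS["molar_mass"])


class UnitError(ValueError):
    """Unknown unit pair or missing species information."""


def _molar_mass(species: str | None) -> float:
    if species is None:
        raise UnitError("conversion to/from molkg requires a species name")
    try:
        return MOLAR_MASS[species]
    except KeyError:
        raise UnitError(f"no molar mass on record for species {species!r}") from None


def convert_units(
    value: float, from_unit: str, to_unit: str, species: str | None = None
) -> float:
    """Convert ``value`` between supported unit pairs.

    Parameters
    ----------
    value:
        Quantity in ``from_unit``.
    from_unit, to_unit:
        One of ``kcal/mol``, ``kJ/mol``, ``ppm_ww``, ``massfrac``,
        ``molkg``.
    species:
        Species symbol, required whenever ``molkg`` is involved.
    """
    if from_unit == to_unit:
        return value
    pair = (from_unit, to_unit)
    if pair == ("kcal/mol", "kJ/mol"):
        return value * KCAL_TO_KJ
    if pair == ("kJ/mol", "kcal/mol"):
        return value / KCAL_TO_KJ
    if pair == ("ppm_ww", "massfrac"):
        return value * 1e-6
    if pair == ("massfrac", "ppm_ww"):
        return value * 1e6
    if pair == ("massfrac", "molkg"):
        # massfrac [kg/kg] * 1000 [g/kg] / M [g/mol] -> mol/kg
        return value * 1e3 / _molar_mass(species)
    if pair == ("molkg", "massfrac"):
        return value * _molar_mass(species) * 1e-3
    if pair == ("ppm_ww", "molkg"):
        return value * 1e-6 * 1e3 / _molar_mass(species)
    if pair == ("molkg", "ppm_ww"):
        return value * _molar_mass(species) * 1e-3 * 1e6
    raise UnitError(f"unsupported unit pair {from_unit!r} -> {to_unit!r}")


def display_round(value: float, ndigits: int = 2) -> float:
    """Round for display (half-even). Internal values are never rounded."""
    return round(value, ndigits)
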