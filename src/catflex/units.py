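"""Energy unit conversion and physical constants.

The pipeline mixes three energy scales by construction: quantum-chemistry
total energies arrive in hartree, conformer-selection windows are quoted in
kcal/mol, and relative-energy plots and Boltzmann factors use kJ/mol.
All conversions pivot through hartree (CODATA 2018 factors).
"""

from __future__ import annotations

HARTREE_TO_KJ_PER_MOL = 2625.499639
HARTREE_TO_KCAL_PER_MOL = 627.509474
HARTREE_TO_EV = 27.211386245988

#: Molar gas constant in kJ/(mol K) — the "k_b" of the Boltzmann weight when
#: energies are expressed per mole.
GAS_CONSTANT_KJ_PER_MOL_K = 8.314462618e-3

_TO_HARTREE = {
    "hartree": 1.0,
    "kJ/mol": 1.0 / HARTREE_TO_KJ_PER_MOL,
    "kcal/mol": 1.0 / HARTREE_TO_KCAL_PER_MOL,
    "eV": 1.0 / HARTREE_TO_EV,
}

ENERGY_UNITS = tuple(_TO_HARTREE)


class UnknownUnitError(ValueError):
    """Raised for an energy unit outside the supported set."""


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy value between hartree, kJ/mol, kcal/mol and eV.

    Round-trips to 1 part in 1e10. Array inputs are supported transparently
    (the conversion is a scalar multiplication).
    """
    if from_unit not in _TO_HARTREE:
        raise UnknownUnitError(f"unknown energy unit {from_unit!r}; expected one of {ENERGY_UNITS}")
    if to_unit not in _TO_HARTREE:
        raise UnknownUnitError(f"unknown energy unit {to_unit!r}; expected one of {ENERGY_UNITS}")
    if from_unit == to_unit:
        return value
    return value * (_TO_HARTREE[from_unit] / _TO_HARTREE[to_unit])
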