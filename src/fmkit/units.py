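"""Unit systems and physical constants.

All in-memory quantities use GROMACS-style internal units: length nm,
energy kJ/mol, charge e, force kJ mol^-1 nm^-1, electrostatic potential
kJ mol^-1 e^-1, field kJ mol^-1 nm^-1 e^-1, angles in degrees in topology
parameter tables (converted to radians inside the force kernels).

Reference-data files emitted by QM engines are typically in Hartree
atomic units; conversion happens once at the I/O boundary.
"""

from __future__ import annotations

# CODATA 2018
BOHR_NM = 0.0529177210903          # nm per bohr
HARTREE_KJ_MOL = 2625.4996394799   # kJ/mol per hartree

#: Coulomb constant 1/(4 pi eps0) in kJ mol^-1 nm e^-2
KC = 138.935458

_AU = {
    "length": BOHR_NM,
    "force": HARTREE_KJ_MOL / BOHR_NM,
    "potential": HARTREE_KJ_MOL,            # hartree/e -> kJ/mol/e
    "field": HARTREE_KJ_MOL / BOHR_NM,
}
_IDENTITY = {"length": 1.0, "force": 1.0, "potential": 1.0, "field": 1.0}

#: factors that convert file values *into* internal units
UNIT_SYSTEMS = {
    "au": _AU,
    "atomic": _AU,
    "internal": _IDENTITY,
    "gromacs": _IDENTITY,
}


def conversion_factors(units: str) -> dict:
    """Per-quantity multiplicative factors taking ``units`` to internal units."""
    try:
        return UNIT_SYSTEMS[units.lower()]
    except KeyError:
        raise ValueError(
            f"unknown unit system {units!r}; known: {sorted(set(UNIT_SYSTEMS))}"
        ) from None
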