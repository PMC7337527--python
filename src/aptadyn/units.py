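"""Physical constants and unit conversions.

Internal conventions: lengths in Å, energies in kcal/mol, charges in
elementary-charge units, angles in degrees at the API surface.
"""

#: Coulomb prefactor in kcal·Å/(mol·e²): elec = K·q_i·q_j/(ε_r·r).
COULOMB_CONSTANT = 332.0636

#: Boltzmann constant in kcal/(mol·K).
KBOLTZ = 0.0019872041

#: 1 kcal (thermochemical) = 4.184 kJ.
KJ_PER_KCAL = 4.184


def kj_to_kcal(e_kj: float) -> float:
    """Convert kJ/mol to kcal/mol (1 kJ/mol = 0.239006 kcal/mol)."""
    return e_kj / KJ_PER_KCAL


def kcal_to_kj(e_kcal: float) -> float:
    """Convert kcal/mol to kJ/mol."""
    return e_kcal * KJ_PER_KCAL


#: Standard atomic masses (amu) for the elements that occur in fixtures.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "NA": 22.990,
    "S": 32.06,
}


def mass_of(element: str) -> float:
    """Atomic mass in amu; raises KeyError for unknown elements."""
    return ATOMIC_MASSES[element.upper()]
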