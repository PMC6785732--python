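"""Unit constants and converters.

Internal units: Angstrom, picosecond, kcal/mol.  Gromacs-style inputs
(nm, kJ/mol) are converted at the boundary.
"""

#: Boltzmann constant, kcal/(mol K)
KB_KCAL_PER_MOL_K = 0.0019872041

#: thermostat temperature of the simulations this package models, K
TEMPERATURE_K = 310.0

#: elementary charge, C (SI exact)
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: 1 eV in kcal/mol; energy gained by a unit charge per mV is this / 1000
EV_KCAL_PER_MOL = 23.060548

NM_TO_ANGSTROM = 10.0
KJ_TO_KCAL = 1.0 / 4.184


def kT(temperature: float = TEMPERATURE_K) -> float:
    """Thermal energy in kcal/mol (0.616 kcal/mol at 310 K)."""
    return KB_KCAL_PER_MOL_K * temperature


def nm_to_angstrom(x: float) -> float:
    return x * NM_TO_ANGSTROM


def kj_to_kcal(x: float) -> float:
    return x * KJ_TO_KCAL


def voltage_force_kcal_per_mol_A(voltage_mV: float, box_z_A: float) -> float:
    """Force on a +1 charge from a potential drop ``voltage_mV`` over ``box_z_A``.

    Returned in kcal/(mol Angstrom); positive voltage drives the charge
    toward +z (the extracellular side in the pore convention).
    """
    return voltage_mV / 1000.0 * EV_KCAL_PER_MOL / box_z_A
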