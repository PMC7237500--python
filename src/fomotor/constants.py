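"""Physical constants and unit conversions.

Internal unit system: lengths in nm, energies in kcal/mol, charges in units
of the elementary charge.  Time is reported in MD steps; bead masses are a
numerical device that sets the diffusive time scale (see docs/methods.md).
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872

#: Coulomb constant, kcal*nm/(mol*e^2)  (332.0637 kcal*A/(mol*e^2))
COULOMB_K = 33.20637

#: 1 kcal/mol expressed in eV (per elementary charge: 1 V = 23.06 kcal/mol/e)
EV_PER_KCAL_MOL = 0.04337

#: 1 kcal/mol expressed in pN*nm
PN_NM_PER_KCAL_MOL = 6.9477

LN10 = 2.302585092994046


def kbt(temperature: float) -> float:
    """Thermal energy in kcal/mol at the given temperature (K)."""
    return KB * temperature


def mv_to_kcal_mol(delta_psi_mv: float) -> float:
    """Convert a membrane potential in mV to kcal/mol per elementary charge."""
    return (delta_psi_mv / 1000.0) / EV_PER_KCAL_MOL


def pn_nm_to_kcal_mol(x: float) -> float:
    """Convert an energy/torque given in pN*nm to kcal/mol (per radian)."""
    return x / PN_NM_PER_KCAL_MOL


def kcal_mol_to_pn_nm(x: float) -> float:
    return x * PN_NM_PER_KCAL_MOL
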