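"""Physical constants and small lookup tables used across the toolkit.

Internal units are fixed everywhere: Ångström for length, elementary
charge (e) for charge, kJ/mol for energy.
"""

from __future__ import annotations

#: Coulomb constant in kJ mol^-1 Å e^-2 (CODATA-derived).
COULOMB_KJ: float = 1389.35458

#: AMBER prmtop stores charges multiplied by this factor (sqrt of the
#: Coulomb constant in kcal/mol units); divide raw CHARGE entries by it
#: to obtain charges in e.
PRMTOP_CHARGE_SCALE: float = 18.2223

#: Default tolerance (Å) added to the sum of covalent radii when
#: inferring bonds from distances.
DEFAULT_BOND_TOLERANCE: float = 0.4

# Covalent radii in Å (Cordero et al. consensus values, single bond).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
    "NA": 1.66,
    "K": 2.03,
    "MG": 1.41,
    "CA": 1.76,
    "ZN": 1.22,
    "FE": 1.32,
}

# Equilibrium bond lengths (Å) used for the default scaled link-atom
# rule: g = d0(Q1-H) / d0(Q1-M1).
STANDARD_BOND_LENGTHS: dict[frozenset[str] | tuple[str, str], float] = {
    ("C", "H"): 1.090,
    ("N", "H"): 1.010,
    ("O", "H"): 0.960,
    ("S", "H"): 1.340,
    ("C", "C"): 1.526,
    ("C", "N"): 1.470,
    ("C", "O"): 1.410,
    ("C", "S"): 1.810,
}


def standard_bond_length(elem_a: str, elem_b: str) -> float:
    """Look up a reference bond length, symmetric in its arguments."""
    a, b = elem_a.upper(), elem_b.upper()
    for key in ((a, b), (b, a)):
        if key in STANDARD_BOND_LENGTHS:
            return STANDARD_BOND_LENGTHS[key]
    raise KeyError(f"no standard bond length for {elem_a}-{elem_b}")


# Formal charges of ionizable residues by (conventional) residue name.
# HIS protonation variants follow AMBER naming; plain HIS is taken as
# the neutral tautomer.  Overridable wherever it is consumed.
RESIDUE_FORMAL_CHARGES: dict[str, int] = {
    "ASP": -1,
    "GLU": -1,
    "LYS": 1,
    "ARG": 1,
    "HIP": 1,
    "HID": 0,
    "HIE": 0,
    "HIS": 0,
    "CYM": -1,
    "CYS": 0,
}

# Theoretical maximum accessible surface areas (Å^2) per residue type
# in an extended Gly-X-Gly context (Tien et al. 2013, "theoretical"
# column).  Used to normalise per-residue SASA into a relative
# exposure fraction for real residue types.
MAX_ASA_GXG: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

# Van der Waals radii (Å) for SASA calculations (Bondi).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
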