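"""Element tables and residue-atom chemistry dictionaries.

Radii are the element-based set used for Shrake-Rupley areas; masses are
standard atomic weights for mass-weighted centers of mass. Donor/acceptor and
charged-group dictionaries encode PDBSum/HBPLUS-style typing for hydrogen
bonds and salt bridges on standard amino acids.
"""

from __future__ import annotations

# Van der Waals radii, Å (probe added separately)
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "ZN": 1.39,
    "MG": 1.73,
    "H": 1.20,
    "D": 1.20,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 1.40,
    "CA": 1.97,
    "NA": 2.27,
    "K": 2.75,
    "MN": 1.40,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "ZN": 65.38, "MG": 24.305,
    "FE": 55.845, "CA": 40.078, "NA": 22.990, "K": 39.098, "MN": 54.938,
    "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}

# Hydrogen-bond donor heavy atoms per residue (backbone N handled separately).
HB_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

# Hydrogen-bond acceptor heavy atoms per residue (backbone O/OXT separate).
HB_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
    "CYS": {"SG"},
}

# Charged groups for salt bridges.
ANIONIC_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
CATIONIC_ATOMS: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}

# Zinc-coordinating side-chain atoms.
ZN_LIGAND_ATOMS: dict[str, set[str]] = {
    "CYS": {"SG"},
    "HIS": {"ND1", "NE2"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def vdw_radius(element: str, overrides: dict[str, float] | None = None) -> float:
    el = element.upper()
    if overrides and el in overrides:
        return overrides[el]
    try:
        return VDW_RADII[el]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {element!r}; pass a radius override"
        ) from None


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 12.011)
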