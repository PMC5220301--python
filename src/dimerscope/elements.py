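"""Reference tables for atoms and residues.

All distances are in nm, masses in Da, areas in nm**2, energies in kcal/mol.
The van der Waals set is a united-atom heavy-atom table so that structures
without hydrogens (typical docking / coarse MD output) can be analysed
directly; hydrogens get their own radius when present.
"""

from __future__ import annotations

# Atomic masses (Da) for the elements that occur in protein heavy atoms
# plus hydrogen and phosphorus.
MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

# United-atom van der Waals radii (nm).
VDW_RADIUS_NM: dict[str, float] = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "H": 0.120,
    "SE": 0.190,
}

# Lennard-Jones well depths per element (kcal/mol); pair minima are taken at
# the sum of the vdW radii with geometric-mean mixing for the depth.
LJ_EPS_KCAL: dict[str, float] = {
    "C": 0.10,
    "N": 0.16,
    "O": 0.20,
    "S": 0.25,
    "P": 0.20,
    "H": 0.02,
    "SE": 0.25,
}

# Theoretical Gly-X-Gly maximum accessible areas (nm**2), used to normalise
# per-residue SASA into a relative exposure in [0, ~1].
MAX_SASA_NM2: dict[str, float] = {
    "ALA": 1.29, "ARG": 2.74, "ASN": 1.95, "ASP": 1.93, "CYS": 1.67,
    "GLU": 2.23, "GLN": 2.25, "GLY": 1.04, "HIS": 2.24, "ILE": 1.97,
    "LEU": 2.01, "LYS": 2.36, "MET": 2.24, "PHE": 2.40, "PRO": 1.59,
    "SER": 1.55, "THR": 1.72, "TRP": 2.85, "TYR": 2.63, "VAL": 1.74,
}

# Hydrogen-bond donor heavy atoms (the attached H points at the acceptor).
# Backbone N is a donor for every residue except proline.
SIDECHAIN_DONOR_ATOMS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "TRP": {"NE1"}, "CYS": {"SG"},
}

# Hydrogen-bond acceptors. Backbone carbonyl O always accepts.
SIDECHAIN_ACCEPTOR_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}

# Formal charges of side-chain terminal groups, +/-1 e spread over the
# terminal atoms. Histidine is neutral unless explicitly protonated.
CHARGED_GROUP_ATOMS: dict[str, dict[str, float]] = {
    "LYS": {"NZ": 1.0},
    "ARG": {"NH1": 0.5, "NH2": 0.5},
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
}
CHARGED_GROUP_ATOMS_HISP: dict[str, float] = {"ND1": 0.5, "NE2": 0.5}

# Atoms whose nitrogen/oxygen pairs define a salt bridge contact.
SALT_BRIDGE_BASIC_ATOMS: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
}
SALT_BRIDGE_BASIC_ATOMS_HISP: set[str] = {"ND1", "NE2"}
SALT_BRIDGE_ACIDIC_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

# Ring atom names used for pi-stacking centroids and normals.
AROMATIC_RING_ATOMS: dict[str, list[str]] = {
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}

AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3: dict[str, str] = {v: k for k, v in AA_3TO1.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def element_from_name(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Handles the common protein cases: a leading digit (e.g. ``1HG1``) marks a
    hydrogen, two-letter elements (SE) are checked first, otherwise the first
    alphabetic character is the element.
    """
    name = atom_name.strip().upper()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():
        return "H"
    if name.startswith("SE"):
        return "SE"
    return name[0]
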