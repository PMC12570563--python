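"""Residue bond templates and chemical parameter tables.

Intra-residue covalent bonds (with bond orders) for the 20 standard
amino acids, the common nucleotides, and the toy residues emitted by the
fixtures module.  Bond order 1 maps to 5 bars in the body-and-bar
multigraph (a free torsion remains), order 2 (including aromatic-ring
and amide bonds, which are planar) to 6 bars (locked).

Also hosts the covalent- and van-der-Waals-radius tables, aromatic ring
definitions for π detection, and the charged-group lists used for salt
bridges and π-cation contacts.
"""

from __future__ import annotations

# -- element parameters -----------------------------------------------------

# Cordero-style covalent radii (Å); fallback distance rule uses
# r(a) + r(b) + COVALENT_TOLERANCE
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "FE": 1.32, "ZN": 1.22, "MG": 1.41, "NA": 1.66, "K": 2.03, "CA": 1.76,
}
COVALENT_TOLERANCE = 0.40

# van der Waals radii (Å) for hydrophobic-contact detection
VDW_RADII = {"C": 1.70, "S": 1.80}

# Lennard-Jones 12-6 per-element parameters (sigma in Å, epsilon in kcal/mol)
LJ_PARAMS = {"C": (3.40, 0.11), "S": (3.60, 0.25)}

_BACKBONE = [("N", "CA", 1), ("CA", "C", 1), ("C", "O", 2)]

# side-chain bonds per residue; aromatic/planar ring bonds carry order 2
_SIDECHAINS = {
    "GLY": [],
    "ALA": [("CA", "CB", 1)],
    "SER": [("CA", "CB", 1), ("CB", "OG", 1)],
    "CYS": [("CA", "CB", 1), ("CB", "SG", 1)],
    "THR": [("CA", "CB", 1), ("CB", "OG1", 1), ("CB", "CG2", 1)],
    "VAL": [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1)],
    "LEU": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1), ("CG", "CD2", 1)],
    "ILE": [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1), ("CG1", "CD1", 1)],
    "MET": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "SD", 1), ("SD", "CE", 1)],
    "PRO": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "N", 1)],
    "PHE": [
        ("CA", "CB", 1), ("CB", "CG", 1),
        ("CG", "CD1", 2), ("CD1", "CE1", 1), ("CE1", "CZ", 2),
        ("CZ", "CE2", 1), ("CE2", "CD2", 2), ("CD2", "CG", 1),
    ],
    "TYR": [
        ("CA", "CB", 1), ("CB", "CG", 1),
        ("CG", "CD1", 2), ("CD1", "CE1", 1), ("CE1", "CZ", 2),
        ("CZ", "CE2", 1), ("CE2", "CD2", 2), ("CD2", "CG", 1),
        ("CZ", "OH", 1),
    ],
    "TRP": [
        ("CA", "CB", 1), ("CB", "CG", 1),
        ("CG", "CD1", 2), ("CD1", "NE1", 1), ("NE1", "CE2", 1),
        ("CE2", "CD2", 2), ("CD2", "CG", 1),
        ("CD2", "CE3", 1), ("CE3", "CZ3", 2), ("CZ3", "CH2", 1),
        ("CH2", "CZ2", 2), ("CZ2", "CE2", 1),
    ],
    "HIS": [
        ("CA", "CB", 1), ("CB", "CG", 1),
        ("CG", "ND1", 1), ("ND1", "CE1", 2), ("CE1", "NE2", 1),
        ("NE2", "CD2", 2), ("CD2", "CG", 1),
    ],
    "ASP": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "OD2", 1)],
    "ASN": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "ND2", 1)],
    "GLU": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
        ("CD", "OE1", 2), ("CD", "OE2", 1),
    ],
    "GLN": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
        ("CD", "OE1", 2), ("CD", "NE2", 1),
    ],
    "LYS": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
        ("CD", "CE", 1), ("CE", "NZ", 1),
    ],
    "ARG": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
        ("CD", "NE", 1), ("NE", "CZ", 1), ("CZ", "NH1", 2), ("CZ", "NH2", 1),
    ],
}

AMINO_ACIDS = set(_SIDECHAINS)

# nucleic-acid sugar-phosphate backbone (ribose numbering with primes)
_NUC_BACKBONE = [
    ("P", "OP1", 2), ("P", "OP2", 1), ("P", "O5'", 1),
    ("O5'", "C5'", 1), ("C5'", "C4'", 1), ("C4'", "O4'", 1), ("C4'", "C3'", 1),
    ("C3'", "O3'", 1), ("C3'", "C2'", 1), ("C2'", "C1'", 1), ("O4'", "C1'", 1),
]
_RIBOSE_EXTRA = [("C2'", "O2'", 1)]

_PURINE = [
    ("N9", "C8", 2), ("C8", "N7", 1), ("N7", "C5", 2), ("C5", "C4", 1),
    ("C4", "N9", 1), ("C4", "N3", 2), ("N3", "C2", 1), ("C2", "N1", 2),
    ("N1", "C6", 1), ("C6", "C5", 2),
]
_PYRIMIDINE = [
    ("N1", "C2", 1), ("C2", "N3", 1), ("N3", "C4", 1), ("C4", "C5", 1),
    ("C5", "C6", 2), ("C6", "N1", 1),
]
_BASES = {
    "A": _PURINE + [("C6", "N6", 1), ("N9", "C1'", 1)],
    "G": _PURINE + [("C6", "O6", 2), ("C2", "N2", 1), ("N9", "C1'", 1)],
    "C": _PYRIMIDINE + [("C2", "O2", 2), ("C4", "N4", 1), ("N1", "C1'", 1)],
    "U": _PYRIMIDINE + [("C2", "O2", 2), ("C4", "O4", 2), ("N1", "C1'", 1)],
    "T": _PYRIMIDINE + [("C2", "O2", 2), ("C4", "O4", 2), ("C5", "C7", 1), ("N1", "C1'", 1)],
}

# toy residues used by the fixtures module
_TOYS = {
    "ETH": [("C1", "C2", 1)],
    "ETE": [("C1", "C2", 2)],
    "BRN": [("C0", "C1", 1), ("C0", "C2", 1), ("C0", "C3", 1), ("C0", "C4", 1)],
}


def _build_templates() -> dict:
    t: dict = {}
    for res, side in _SIDECHAINS.items():
        t[res] = _BACKBONE + side
    for base, bonds in _BASES.items():
        rna = base in ("A", "G", "C", "U")
        sugar = _NUC_BACKBONE + (_RIBOSE_EXTRA if rna else [])
        t[base] = sugar + bonds
        t["D" + base] = _NUC_BACKBONE + bonds  # deoxy form
    t.update(_TOYS)
    return t


#: residue name -> list of (atom_name, atom_name, bond_order)
RESIDUE_TEMPLATES = _build_templates()

NUCLEOTIDES = {r for r in RESIDUE_TEMPLATES if r in _BASES or (r[0] == "D" and r[1:] in _BASES)}

# -- aromatic rings for π detection ----------------------------------------

AROMATIC_RINGS = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"],
    ],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
}
_PURINE_RINGS = [["N1", "C2", "N3", "C4", "C5", "C6"], ["C4", "C5", "N7", "C8", "N9"]]
_PYRIMIDINE_RING = [["N1", "C2", "N3", "C4", "C5", "C6"]]
for _b in ("A", "G"):
    AROMATIC_RINGS[_b] = _PURINE_RINGS
    AROMATIC_RINGS["D" + _b] = _PURINE_RINGS
for _b in ("C", "U", "T"):
    AROMATIC_RINGS[_b] = _PYRIMIDINE_RING
    AROMATIC_RINGS["D" + _b] = _PYRIMIDINE_RING

# -- charged groups ---------------------------------------------------------

# (residue, atom) pairs carrying formal positive/negative charge at pH 7
CHARGED_POSITIVE = {
    ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
    ("LYS", "NZ"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
CHARGED_NEGATIVE = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}
#: cation centers for π-cation contacts
PI_CATIONS = {("LYS", "NZ"), ("ARG", "CZ")}

#: backbone representative used for residue-level tie-breaks
BACKBONE_ATOM = {"protein": "CA", "nucleic": "C1'"}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
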