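"""Chemical typing templates for the 20 standard amino-acid residues.

Detectors classify receptor atoms by name against these tables rather than
inferring connectivity from coordinates: backbone N is a donor (amide H named
``H``), backbone O an acceptor, and side-chain roles follow standard residue
topology.  Apolar atoms are non-aromatic carbons whose bonded neighbours are
only carbon/hydrogen; aromatic ring carbons participate through the pi channel
instead (ring templates below), never as alkyl partners.
"""

from __future__ import annotations

# donor heavy atom -> names of its polar hydrogens (used for the D-H...A angle
# when the structure carries explicit hydrogens)
SIDECHAIN_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TRP": {"NE1": ("HE1",)},
    "TYR": {"OH": ("HH",)},
}

SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

#: aromatic ring systems as ordered atom-name cycles
AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TYR": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    ),
    "HIS": (("CG", "ND1", "CE1", "NE2", "CD2"),),
}

#: non-aromatic carbons bonded only to C/H (hydrophobic alkyl partners)
APOLAR_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "HIS": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD"),
    "MET": ("CB",),
    "PHE": ("CB",),
    "PRO": ("CB", "CG"),
    "THR": ("CG2",),
    "TRP": ("CB",),
    "TYR": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
}

#: anionic side-chain groups: atoms whose centroid carries the formal charge
ANION_GROUPS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: cationic side-chain groups (HIS added at runtime when flagged cationic)
CATION_GROUPS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}

HIS_CATION_GROUP: tuple[str, ...] = ("ND1", "NE2")

#: thioether/thiol sulfurs (pi-sulfur partners)
SULFUR_ATOMS: dict[str, tuple[str, ...]] = {
    "MET": ("SD",),
    "CYS": ("SG",),
}

BACKBONE_DONOR = ("N", ("H", "H1", "H2", "H3"))
BACKBONE_ACCEPTORS = ("O", "OXT")
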