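"""Reference inputs for the GPER/Bcl-2 dual-target screen.

Structures of the tetrahydroquinoline scaffold and the sulfonamide
nucleophiles used in the compound design, and the literature-derived Bcl-2
binding-site residue sets used for the binding-mode similarity worked example.
"""

from __future__ import annotations

from .chem import Molecule

#: (3aS,4R,9bR)-4-(6-bromobenzo[d][1,3]dioxol-5-yl)-3a,4,5,9b-tetrahydro-3H-
#: cyclopenta[c]quinoline-8-carboxylic acid: the GPER pharmacophore scaffold
#: carrying the carboxylic acid that is decorated by amide coupling.
G1_PABA_SMILES = "OC(=O)c1ccc2c(c1)[C@@H]1CC=C[C@@H]1[C@@H](c1cc3c(cc1Br)OCO3)N2"

#: Nucleophiles used for the two synthesized leads: an amide bond with the
#: 4-methyl sulfonamide gives compound 6, with the 4-chloro one compound 37.
SULFONAMIDE_SMILES = {
    "4-methylbenzenesulfonamide": "Cc1ccc(cc1)S(N)(=O)=O",
    "4-chlorobenzenesulfonamide": "Clc1ccc(cc1)S(N)(=O)=O",
}


def g1_paba() -> Molecule:
    return Molecule.from_smiles(G1_PABA_SMILES, "G1-PABA")


def sulfonamide_nucleophiles() -> list[Molecule]:
    return [
        Molecule.from_smiles(smi, name) for name, smi in SULFONAMIDE_SMILES.items()
    ]


#: Bcl-2 residues contacted by the control ligand Gossypol in its docked
#: binding mode (BH1/BH3 groove).
GOSSYPOL_BCL2_RESIDUES = frozenset(
    {
        "Asp111",
        "Phe112",
        "Met115",
        "Gln118",
        "Leu119",
        "His120",
        "Phe130",
        "Ala131",
        "Thr132",
        "Val133",
        "Leu137",
        "Phe153",
        "Met157",
    }
)

#: Bcl-2 residues contacted by both designed leads (compounds 6 and 37),
#: bounding the BH3-mimetic binding site they reach.
LEADS_BCL2_RESIDUES = frozenset(
    {
        "Phe130",
        "Ala131",
        "Thr132",
        "Val133",
        "Leu137",
        "Phe153",
        "Met157",
    }
)
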