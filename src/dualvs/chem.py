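"""Ligand chemistry: formula arithmetic, exact masses, properties, amide enumeration.

Molecules are backed by RDKit; the formula type and the condensation
enumeration are implemented here because they carry the design step of the
screen (decorating a carboxylic-acid scaffold with sulfonamide/amine
nucleophiles) and because exact-mass bookkeeping must be explicit about the
neutral-species convention.

Conventions
-----------
* Masses and formulas always refer to the NEUTRAL molecule.  Adduct masses
  ([M+H]+, [M-H]-) are available only through :func:`adduct_mass`.
* Monoisotopic masses are sums of most-abundant-isotope masses taken from
  RDKit's periodic table (NIST-derived, >=6 decimals).
* Properties: molecular weight from standard average atomic weights, log P by
  the Wildman-Crippen atomic-contribution scheme, TPSA by the Ertl
  fragment-contribution scheme, HBD/HBA by the Lipinski N/O counting rules.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

__all__ = [
    "ElementalFormula",
    "FormulaError",
    "Molecule",
    "PropertySet",
    "adduct_mass",
    "compute_properties",
    "enumerate_amide_products",
    "molecular_formula",
    "monoisotopic_mass",
    "parse_formula",
    "properties_table",
]

_PT = Chem.GetPeriodicTable()

#: mass of a proton, Da (CODATA); used for ESI adduct arithmetic
PROTON_MASS = 1.007276466

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible elemental formulas."""


def _is_element(symbol: str) -> bool:
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition of a neutral species.

    Supports addition/subtraction (formula arithmetic for condensation
    reactions) and renders in Hill order: C, H, then other elements
    alphabetically (all alphabetical when carbon is absent).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if not _is_element(el):
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise FormulaError(
                    f"cannot remove {n} {el} from {self}: only {merged.get(el, 0)} present"
                )
            merged[el] = left
        return ElementalFormula(merged)

    def __str__(self) -> str:
        return self.hill()

    def hill(self) -> str:
        """Canonical Hill-order rendering, e.g. ``C27H23BrN2O5S``."""
        parts = []
        order: list[str]
        if "C" in self.counts:
            order = ["C"] + (["H"] if "H" in self.counts else [])
            order += sorted(el for el in self.counts if el not in ("C", "H"))
        else:
            order = sorted(self.counts)
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


WATER = ElementalFormula({"H": 2, "O": 1})


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C27H23BrN2O5S"``.

    Raises :class:`FormulaError` on empty input, unknown element symbols or
    explicit zero multipliers.  Round-trips with :meth:`ElementalFormula.hill`
    on canonical formulas.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula at {text[pos:]!r}")
        symbol, digits = match.groups()
        if not _is_element(symbol):
            raise FormulaError(f"unknown element symbol: {symbol!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero multiplier for {symbol} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"trailing junk in formula: {text[pos:]!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Sum of most-abundant-isotope masses, in Da.

    Additive over formula concatenation; the empty formula has mass 0.
    """
    total = 0.0
    for el, n in formula.counts.items():
        m = _PT.GetMostCommonIsotopeMass(el)
        if m <= 0.0:
            raise FormulaError(f"no isotope mass tabulated for {el}")
        total += n * m
    return total


_ADDUCTS = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
}


def adduct_mass(formula: ElementalFormula, adduct: str) -> float:
    """Monoisotopic m/z of a singly charged ESI adduct of the neutral formula."""
    try:
        delta = _ADDUCTS[adduct]
    except KeyError:
        raise FormulaError(f"unsupported adduct {adduct!r}; known: {sorted(_ADDUCTS)}")
    return monoisotopic_mass(formula) + delta


@dataclass
class Molecule:
    """A ligand: an identifier plus an RDKit topology (and optional 3D coords)."""

    id: str
    rdmol: Chem.Mol

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str | None = None) -> "Molecule":
        m = Chem.MolFromSmiles(smiles)
        if m is None:
            raise ValueError(f"invalid SMILES: {smiles!r}")
        return cls(id=mol_id if mol_id is not None else smiles, rdmol=m)

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)

    @property
    def n_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    def formula(self) -> ElementalFormula:
        return molecular_formula(self)


def molecular_formula(mol: Molecule) -> ElementalFormula:
    """Neutral elemental formula including implicit hydrogens."""
    counts: dict[str, int] = {}
    for atom in mol.rdmol.GetAtoms():
        el = atom.GetSymbol()
        counts[el] = counts.get(el, 0) + 1
        nh = atom.GetTotalNumHs(includeNeighbors=False)
        if nh:
            counts["H"] = counts.get("H", 0) + nh
    return ElementalFormula(counts)


@dataclass(frozen=True)
class PropertySet:
    """Drug-likeness descriptors used by the point scoring."""

    molecular_weight: float  # g/mol, average atomic weights
    log_p: float             # Wildman-Crippen estimate
    hbd: int                 # Lipinski N-H/O-H donor count
    hba: int                 # Lipinski N/O acceptor count
    tpsa: float              # Ertl topological polar surface area, A^2

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.hbd < 0 or self.hba < 0 or self.tpsa < 0:
            raise ValueError("hbd/hba/tpsa must be non-negative")


def compute_properties(mol: Molecule) -> PropertySet:
    """Physicochemical property set of a ligand.

    Raises ``ValueError`` for an empty molecule.  Invariant to atom ordering
    (all descriptors are sums of per-atom/fragment contributions).
    """
    m = mol.rdmol
    if m.GetNumAtoms() == 0:
        raise ValueError(f"molecule {mol.id!r} has no atoms")
    return PropertySet(
        molecular_weight=Descriptors.MolWt(m),
        log_p=Crippen.MolLogP(m),
        hbd=Lipinski.NumHDonors(m),
        hba=Lipinski.NumHAcceptors(m),
        tpsa=Descriptors.TPSA(m),
    )


# -- amide enumeration --------------------------------------------------------

# carboxylic acid: carbonyl C, carbonyl O, hydroxyl O
_ACID = Chem.MolFromSmarts("[CX3:1](=[OX1])[OX2H1]")
# reactive N-H nucleophile: primary amine on carbon, or sulfonamide N-H
_NUCLEOPHILE = Chem.MolFromSmarts("[NX3;H2,H1;$([N][#6]),$([N]S(=O)=O)]")


def enumerate_amide_products(
    acid: Molecule, nucleophiles: Iterable[Molecule]
) -> list[Molecule]:
    """Condense a carboxylic acid with N-H nucleophiles into amides.

    For every (acid carboxyl site, nucleophile N-H site) pair one product is
    emitted, ordered by acid site index then nucleophile order then
    nucleophile site index.  The product formula is exactly
    ``acid + nucleophile - H2O`` (water eliminated).

    A nucleophile with no reactive N-H is skipped with a warning; an acid with
    no carboxyl group is an error.
    """
    nucleophiles = list(nucleophiles)
    acid_sites = acid.rdmol.GetSubstructMatches(_ACID)
    if not acid_sites:
        raise ValueError(f"acid {acid.id!r} has no carboxylic-acid group")
    products: list[Molecule] = []
    for c_idx, o_carbonyl, o_hydroxyl in acid_sites:
        for nuc in nucleophiles:
            n_sites = nuc.rdmol.GetSubstructMatches(_NUCLEOPHILE)
            if not n_sites:
                warnings.warn(
                    f"nucleophile {nuc.id!r} has no reactive N-H; skipped",
                    stacklevel=2,
                )
                continue
            for (n_idx,) in n_sites:
                combo = Chem.RWMol(Chem.CombineMols(acid.rdmol, nuc.rdmol))
                offset = acid.rdmol.GetNumAtoms()
                n_atom = combo.GetAtomWithIdx(offset + n_idx)
                n_atom.SetNumExplicitHs(max(n_atom.GetTotalNumHs() - 1, 0))
                n_atom.SetNoImplicit(True)
                combo.AddBond(c_idx, offset + n_idx, Chem.BondType.SINGLE)
                combo.RemoveAtom(o_hydroxyl)  # leaves as part of water
                product = combo.GetMol()
                Chem.SanitizeMol(product)
                suffix = "" if len(acid_sites) == 1 and len(n_sites) == 1 else (
                    f"@a{c_idx}n{n_idx}"
                )
                products.append(
                    Molecule(id=f"{acid.id}+{nuc.id}{suffix}", rdmol=product)
                )
    return products


# -- file I/O -----------------------------------------------------------------

def read_sdf(path: str | Path) -> list[Molecule]:
    """Read molecules from an SDF (V2000) file; ids from the title line."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    mols = []
    for i, m in enumerate(supplier):
        if m is None:
            raise ValueError(f"unreadable record {i} in {path}")
        name = m.GetProp("_Name") if m.HasProp("_Name") and m.GetProp("_Name") else f"mol{i}"
        mols.append(Molecule(id=name, rdmol=m))
    return mols


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            m = Chem.Mol(mol.rdmol)
            m.SetProp("_Name", mol.id)
            writer.write(m)
    finally:
        writer.close()


def properties_table(mols: Iterable[Molecule]):
    """Property table for a ligand set (columns ligand_id,mw,logp,hbd,hba,tpsa)."""
    import pandas as pd

    rows = []
    for mol in mols:
        p = compute_properties(mol)
        rows.append(
            {
                "ligand_id": mol.id,
                "mw": p.molecular_weight,
                "logp": p.log_p,
                "hbd": p.hbd,
                "hba": p.hba,
                "tpsa": p.tpsa,
            }
        )
    return pd.DataFrame(rows, columns=["ligand_id", "mw", "logp", "hbd", "hba", "tpsa"])
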