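"""Receptor/pose I/O: PDB receptors, SDF/PDB docked poses, docking-energy CSV.

Residue identity is (chain, number-string, 3-letter name) with the numbering
preserved verbatim from the source file (insertion codes appended), so that
fingerprint residues can be compared against published labels like Phe206.
Coordinates are Angstrom in the receptor frame; docked poses are assumed to be
written in that same frame by the docking engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "Atom",
    "EnergyTable",
    "Pose",
    "ReceptorStructure",
    "Residue",
    "ResidueId",
    "read_energy_table",
    "read_poses",
    "read_receptor",
    "write_receptor",
]


class ResidueId(NamedTuple):
    chain: str
    number: str  # residue number as printed, insertion code appended
    name: str    # 3-letter code

    @property
    def label(self) -> str:
        """Publication-style label, e.g. ``Phe206``."""
        return self.name.capitalize() + self.number


class Atom(NamedTuple):
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Residue:
    rid: ResidueId
    atoms: list[Atom]

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class ReceptorStructure:
    """Ordered residues of one receptor model."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        seen = set()
        for res in self.residues:
            key = (res.rid.chain, res.rid.number)
            if key in seen:
                raise ValueError(f"duplicate residue {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Pose:
    """A ligand's docked coordinates in the receptor frame.

    ``topology`` carries bond orders/aromaticity when the pose came from a
    connection-table format (SDF); atom order matches ``atoms``.
    """

    ligand_id: str
    atoms: list[Atom]
    binding_energy: Optional[float] = None
    topology: Optional[Chem.Mol] = None

    def __post_init__(self) -> None:
        if not any(a.element != "H" for a in self.atoms):
            raise ValueError(f"pose {self.ligand_id!r} has no heavy atoms")
        if self.binding_energy is not None and not math.isfinite(self.binding_energy):
            raise ValueError(f"pose {self.ligand_id!r}: non-finite binding energy")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class EnergyTable:
    """Docking energies keyed by (ligand_id, target_id), kcal/mol, signed."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, ligand_id: str, target_id: str) -> Optional[float]:
        return self.entries.get((ligand_id, target_id))

    def add(self, ligand_id: str, target_id: str, energy: float) -> None:
        key = (ligand_id, target_id)
        if key in self.entries:
            raise ValueError(f"duplicate energy entry for {key}")
        if not math.isfinite(energy):
            raise ValueError(f"non-finite energy for {key}")
        self.entries[key] = float(energy)


def read_energy_table(path: str | Path) -> EnergyTable:
    """Read a ``ligand_id,target_id,binding_energy`` CSV (sign preserved)."""
    df = pd.read_csv(path, dtype={"ligand_id": str, "target_id": str})
    required = {"ligand_id", "target_id", "binding_energy"}
    if not required.issubset(df.columns):
        raise ValueError(f"energy CSV must have columns {sorted(required)}")
    table = EnergyTable()
    for row in df.itertuples(index=False):
        energy = float(row.binding_energy)
        if not math.isfinite(energy):
            raise ValueError(
                f"non-numeric energy for ({row.ligand_id}, {row.target_id})"
            )
        table.add(str(row.ligand_id), str(row.target_id), energy)
    return table


def read_receptor(path: str | Path) -> ReceptorStructure:
    """Parse ATOM/HETATM records of the first model of a PDB file.

    Alternate locations are resolved to the highest-occupancy copy of each
    atom name; hydrogens are retained when present.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            # per atom name keep the highest-occupancy altloc
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [
                Atom(
                    a.name,
                    a.element.name if a.element.name else "X",
                    (a.pos.x, a.pos.y, a.pos.z),
                )
                for a in best.values()
            ]
            for a in atoms:
                if not all(math.isfinite(c) for c in a.xyz):
                    raise ValueError(f"non-finite coordinates in {path}")
            number = str(res.seqid.num) + (
                res.seqid.icode.strip() if res.seqid.icode else ""
            )
            residues.append(
                Residue(ResidueId(chain.name, number, res.name), atoms)
            )
    if not residues:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    return ReceptorStructure(residues)


def write_receptor(receptor: ReceptorStructure, path: str | Path) -> None:
    """Write a receptor as plain PDB ATOM records (3-decimal coordinates)."""
    lines = []
    serial = 0
    for res in receptor.residues:
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.xyz
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {res.rid.name:<3.3s} "
                f"{res.rid.chain:1.1s}{int(res.rid.number):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2.2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pose_from_rdmol(
    mol: Chem.Mol, ligand_id: str, energy: Optional[float]
) -> Pose:
    if mol.GetNumConformers() == 0:
        raise ValueError(f"pose {ligand_id!r} has no 3D coordinates")
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append(
            Atom(
                f"{atom.GetSymbol()}{atom.GetIdx() + 1}",
                atom.GetSymbol(),
                (pos.x, pos.y, pos.z),
            )
        )
    return Pose(ligand_id, atoms, energy, topology=mol)


def read_poses(
    path: str | Path,
    energies: Optional[EnergyTable] = None,
    target_id: str = "",
    ligand_id: Optional[str] = None,
) -> list[Pose]:
    """Read docked poses from SDF (multi-pose) or PDB (single pose).

    Poses are returned in file order with binding energies attached from
    ``energies`` where present (absent otherwise).  Duplicate ligand ids
    within one file are an error.
    """
    path = Path(path)
    poses: list[Pose] = []
    if path.suffix.lower() in (".sdf", ".sd", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unreadable pose record {i} in {path}")
            lid = (
                mol.GetProp("_Name")
                if mol.HasProp("_Name") and mol.GetProp("_Name")
                else f"pose{i}"
            )
            energy = energies.get(lid, target_id) if energies else None
            poses.append(_pose_from_rdmol(mol, lid, energy))
    else:
        lid = ligand_id if ligand_id is not None else path.stem
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        atoms = []
        if len(st) > 0:
            for chain in st[0]:
                for res in chain:
                    for a in res:
                        atoms.append(
                            Atom(a.name, a.element.name or "X", (a.pos.x, a.pos.y, a.pos.z))
                        )
        if not atoms:
            raise ValueError(f"no atoms in pose file {path}")
        energy = energies.get(lid, target_id) if energies else None
        poses.append(Pose(lid, atoms, energy))
    ids = [p.ligand_id for p in poses]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ligand ids in {path}: {dup}")
    return poses
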