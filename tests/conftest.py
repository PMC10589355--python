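"""Shared fixtures and geometric helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from dualvs.interactions import GeometryParams
from dualvs.structio import Atom, Pose, ReceptorStructure, Residue, ResidueId
from dualvs.synthetic import _LigandBuilder, _benzene


@pytest.fixture
def params() -> GeometryParams:
    return GeometryParams()


def make_residue(name: str, atoms: list[tuple[str, str, tuple]], number: str = "1",
                 chain: str = "A") -> Residue:
    return Residue(
        ResidueId(chain, number, name),
        [Atom(n, el, tuple(map(float, xyz))) for n, el, xyz in atoms],
    )


def make_pose_from_fragments(fragments, ligand_id="lig") -> Pose:
    """Build a pose from (elements, bonds, coords) fragment triples."""
    from dualvs.structio import _pose_from_rdmol

    builder = _LigandBuilder()
    for els, bonds, coords in fragments:
        builder.add_fragment(els, bonds, [np.asarray(c, dtype=float) for c in coords])
    mol = builder.finish(ligand_id)
    return _pose_from_rdmol(mol, ligand_id, None)


def benzene_fragment(center, normal=None):
    """Benzene ring fragment centered at `center`, default plane z=const."""
    center = np.asarray(center, dtype=float)
    if normal is None:
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
    else:
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, n)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, n) * n
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
    return _benzene(center, e1, e2)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def rigid_transform(receptor: ReceptorStructure, pose: Pose,
                    rot: np.ndarray, trans: np.ndarray):
    """Apply the same rotation + translation to receptor and pose."""
    new_residues = []
    for res in receptor.residues:
        new_atoms = [
            Atom(a.name, a.element, tuple(rot @ np.asarray(a.xyz) + trans))
            for a in res.atoms
        ]
        new_residues.append(Residue(res.rid, new_atoms))
    new_pose_atoms = [
        Atom(a.name, a.element, tuple(rot @ np.asarray(a.xyz) + trans))
        for a in pose.atoms
    ]
    return (
        ReceptorStructure(new_residues),
        Pose(pose.ligand_id, new_pose_atoms, pose.binding_energy, pose.topology),
    )


def receptor_phe_ring(center, normal, number="1", with_cb=True) -> Residue:
    """Idealized PHE aromatic ring (radius 1.39 A) with given plane normal."""
    center = np.asarray(center, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms = []
    for k, name in enumerate(names):
        ang = np.pi / 3.0 * k
        atoms.append(
            (name, "C", tuple(center + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2)))
        )
    if with_cb:
        atoms.append(("CB", "C", tuple(center + 3.0 * n)))
    return make_residue("PHE", atoms, number=number)
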