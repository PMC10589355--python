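"""Geometric detection and typing of protein-ligand interactions.

Every detector is a plain all-pairs geometric predicate over typed chemical
features (donors/acceptors, aromatic ring planes, apolar atoms, charged
groups, thioether sulfurs).  The union of typed records plus generic heavy-atom
contacts forms the per-ligand interacting-residue fingerprint that the
binding-mode similarity score consumes.

All cutoffs are inclusive and live in :class:`GeometryParams`; none of them is
hard-coded in a detector.  A k-d-tree residue prefilter is available as an
acceleration and is required (and tested) to reproduce the all-pairs result
record-for-record.

Geometry conventions: distances in Angstrom; ring planes fitted by SVD;
interplanar and axial angles folded into [0, 90] degrees; the hydrogen-bond
angle is the D-H...A angle at the hydrogen, in [0, 180] degrees, evaluated
only when an explicit polar hydrogen is present (distance-only fallback
otherwise, as docked structures frequently lack hydrogens).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .residues import (
    ANION_GROUPS,
    APOLAR_ATOMS,
    AROMATIC_RINGS,
    BACKBONE_ACCEPTORS,
    BACKBONE_DONOR,
    CATION_GROUPS,
    HIS_CATION_GROUP,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    SULFUR_ATOMS,
)
from .structio import Pose, ReceptorStructure, Residue, ResidueId

__all__ = [
    "ContactFingerprint",
    "GeometryParams",
    "INTERACTION_TYPES",
    "InteractionRecord",
    "detect_aromatic",
    "detect_charged_special",
    "detect_hbonds",
    "detect_nonpolar",
    "fingerprint",
]

INTERACTION_TYPES = (
    "hbond",
    "pi_pi_stacked",
    "pi_pi_tshaped",
    "pi_alkyl",
    "alkyl",
    "pi_cation",
    "pi_anion",
    "pi_sulfur",
    "halogen",
    "generic_contact",
)

HALOGENS = ("F", "Cl", "Br", "I")
HALOGEN_BOND_DONORS = ("Cl", "Br", "I")


@dataclass(frozen=True)
class GeometryParams:
    """Named geometric cutoffs/windows; boundaries are inclusive."""

    hbond_distance: float = 3.5        # heavy donor-acceptor, A
    hbond_angle: float = 120.0         # minimum D-H...A angle, deg (H explicit)
    pi_pi_distance: float = 5.5        # ring centroid-centroid, A
    pi_stacked_angle: float = 30.0     # interplanar angle <= for stacked, deg
    pi_tshaped_angle: tuple[float, float] = (60.0, 90.0)  # window, deg
    pi_alkyl_distance: float = 5.0     # centroid to apolar atom, A
    pi_cation_distance: float = 5.0    # centroid to cation-group centroid, A
    pi_anion_distance: float = 5.0     # centroid to anion-group centroid, A
    pi_sulfur_distance: float = 5.5    # centroid to S, A
    alkyl_distance: float = 4.5        # apolar atom-atom, A
    halogen_distance: float = 4.5      # ligand Cl/Br/I to receptor O/N/S, A
    generic_distance: float = 4.0      # any heavy atom-atom, A
    his_cationic: bool = False         # treat His as protonated/cationic

    def max_cutoff(self) -> float:
        return max(
            self.hbond_distance,
            self.pi_pi_distance,
            self.pi_alkyl_distance,
            self.pi_cation_distance,
            self.pi_anion_distance,
            self.pi_sulfur_distance,
            self.alkyl_distance,
            self.halogen_distance,
            self.generic_distance,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pi_tshaped_angle"] = list(self.pi_tshaped_angle)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeometryParams":
        data = dict(data)
        if "pi_tshaped_angle" in data:
            data["pi_tshaped_angle"] = tuple(data["pi_tshaped_angle"])
        return cls(**data)


@dataclass(frozen=True)
class InteractionRecord:
    residue: ResidueId
    interaction_type: str
    distance: float
    receptor_atoms: tuple[str, ...]
    ligand_atoms: tuple[str, ...]
    angle: Optional[float] = None

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class ContactFingerprint:
    """Typed records plus the order-free interacting-residue set."""

    ligand_id: str
    target_id: str
    records: list[InteractionRecord] = field(default_factory=list)
    extra_residues: frozenset = frozenset()  # for annotation-derived sets

    @property
    def residues(self) -> frozenset:
        return frozenset(r.residue for r in self.records) | self.extra_residues

    @property
    def typed_pairs(self) -> frozenset:
        """Deduplicated (residue, type) pairs, generic contacts excluded."""
        return frozenset(
            (r.residue, r.interaction_type)
            for r in self.records
            if r.interaction_type != "generic_contact"
        )

    @classmethod
    def from_residues(
        cls, ligand_id: str, target_id: str, residues: Iterable
    ) -> "ContactFingerprint":
        return cls(ligand_id, target_id, [], frozenset(residues))

    def to_json_dict(self) -> dict:
        return {
            "ligand_id": self.ligand_id,
            "target_id": self.target_id,
            "residues": sorted(
                r.label if isinstance(r, ResidueId) else str(r)
                for r in self.residues
            ),
            "records": [
                {
                    "residue": r.residue.label,
                    "type": r.interaction_type,
                    "distance": round(r.distance, 4),
                    "angle": None if r.angle is None else round(r.angle, 2),
                    "receptor_atoms": list(r.receptor_atoms),
                    "ligand_atoms": list(r.ligand_atoms),
                }
                for r in sorted(
                    self.records,
                    key=lambda r: (r.residue, r.interaction_type, r.distance),
                )
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1) + "\n")


# -- feature extraction -------------------------------------------------------

def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal (SVD plane fit) of a ring atom set."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosang = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _angle_at(h: np.ndarray, d: np.ndarray, a: np.ndarray) -> float:
    v1, v2 = d - h, a - h
    cosang = float(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    )
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class _Ring:
    atom_names: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray


@dataclass
class _ReceptorFeatures:
    residue: Residue
    donors: list[tuple[str, np.ndarray, list[np.ndarray]]]  # name, xyz, H xyzs
    acceptors: list[tuple[str, np.ndarray]]
    rings: list[_Ring]
    apolar: list[tuple[str, np.ndarray]]
    anion_groups: list[tuple[tuple[str, ...], np.ndarray]]
    cation_groups: list[tuple[tuple[str, ...], np.ndarray]]
    sulfurs: list[tuple[str, np.ndarray]]
    ons_atoms: list[tuple[str, np.ndarray]]  # O/N/S, halogen-bond acceptors
    heavy: list[tuple[str, np.ndarray]]


def _residue_features(res: Residue, params: GeometryParams) -> _ReceptorFeatures:
    name = res.rid.name.upper()
    xyz = {a.name: np.asarray(a.xyz, dtype=float) for a in res.atoms}

    donors = []
    donor_map = dict(SIDECHAIN_DONORS.get(name, {}))
    bb_atom, bb_hs = BACKBONE_DONOR
    if bb_atom in xyz:
        donor_map.setdefault(bb_atom, bb_hs)
    for heavy, h_names in donor_map.items():
        if heavy in xyz:
            hs = [xyz[h] for h in h_names if h in xyz]
            donors.append((heavy, xyz[heavy], hs))

    acceptors = [
        (a, xyz[a])
        for a in SIDECHAIN_ACCEPTORS.get(name, ()) + BACKBONE_ACCEPTORS
        if a in xyz
    ]

    rings = []
    for ring_names in AROMATIC_RINGS.get(name, ()):
        if all(n in xyz for n in ring_names):
            coords = np.array([xyz[n] for n in ring_names])
            centroid, normal = _ring_geometry(coords)
            rings.append(_Ring(ring_names, centroid, normal))

    apolar = [(a, xyz[a]) for a in APOLAR_ATOMS.get(name, ()) if a in xyz]

    anion_groups = []
    group = ANION_GROUPS.get(name)
    if group and all(g in xyz for g in group):
        anion_groups.append((group, np.array([xyz[g] for g in group]).mean(axis=0)))

    cation_defs = dict(CATION_GROUPS)
    if params.his_cationic:
        cation_defs["HIS"] = HIS_CATION_GROUP
    cation_groups = []
    cgroup = cation_defs.get(name)
    if cgroup and all(g in xyz for g in cgroup):
        cation_groups.append((cgroup, np.array([xyz[g] for g in cgroup]).mean(axis=0)))

    sulfurs = [(a, xyz[a]) for a in SULFUR_ATOMS.get(name, ()) if a in xyz]

    heavy = [
        (a.name, np.asarray(a.xyz, dtype=float))
        for a in res.atoms
        if a.element != "H"
    ]
    ons_atoms = [
        (a.name, np.asarray(a.xyz, dtype=float))
        for a in res.atoms
        if a.element in ("O", "N", "S")
    ]
    return _ReceptorFeatures(
        res, donors, acceptors, rings, apolar, anion_groups, cation_groups,
        sulfurs, ons_atoms, heavy,
    )


@dataclass
class _LigandFeatures:
    donors: list[tuple[str, np.ndarray, list[np.ndarray]]]
    acceptors: list[tuple[str, np.ndarray]]
    rings: list[_Ring]
    apolar: list[tuple[str, np.ndarray]]
    halogen_donors: list[tuple[str, np.ndarray]]
    anions: list[tuple[str, np.ndarray]]
    cations: list[tuple[str, np.ndarray]]
    sulfurs: list[tuple[str, np.ndarray]]
    heavy: list[tuple[str, np.ndarray]]


def _ligand_features(pose: Pose) -> _LigandFeatures:
    names = [a.name for a in pose.atoms]
    coords = pose.coords()
    elements = [a.element for a in pose.atoms]
    heavy = [
        (names[i], coords[i]) for i in range(len(names)) if elements[i] != "H"
    ]
    halogen_donors = [
        (names[i], coords[i])
        for i in range(len(names))
        if elements[i] in HALOGEN_BOND_DONORS
    ]
    sulfurs = [
        (names[i], coords[i]) for i in range(len(names)) if elements[i] == "S"
    ]

    mol = pose.topology
    if mol is None or mol.GetNumAtoms() != len(pose.atoms):
        # element-only fallback (no connectivity): distance-only donors,
        # every N/O polar, every carbon a potential alkyl partner, no rings
        donors = [
            (names[i], coords[i], [])
            for i in range(len(names))
            if elements[i] in ("N", "O")
        ]
        acceptors = [
            (names[i], coords[i])
            for i in range(len(names))
            if elements[i] in ("N", "O")
        ]
        apolar = [
            (names[i], coords[i])
            for i in range(len(names))
            if elements[i] == "C" or elements[i] in HALOGENS
        ]
        return _LigandFeatures(
            donors, acceptors, [], apolar, halogen_donors, [], [], sulfurs, heavy
        )

    donors = []
    acceptors = []
    apolar = []
    anions = []
    cations = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym in ("N", "O"):
            acceptors.append((names[i], coords[i]))
            if atom.GetTotalNumHs(includeNeighbors=True) > 0:
                h_coords = [
                    coords[nb.GetIdx()]
                    for nb in atom.GetNeighbors()
                    if nb.GetSymbol() == "H"
                ]
                donors.append((names[i], coords[i], h_coords))
        if sym == "C" and not atom.GetIsAromatic():
            if all(nb.GetSymbol() in ("C", "H") for nb in atom.GetNeighbors()):
                apolar.append((names[i], coords[i]))
        if sym in HALOGENS:
            apolar.append((names[i], coords[i]))
        if atom.GetFormalCharge() < 0:
            anions.append((names[i], coords[i]))
        elif atom.GetFormalCharge() > 0:
            cations.append((names[i], coords[i]))

    rings = []
    for ring_idx in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring_idx):
            ring_coords = coords[list(ring_idx)]
            centroid, normal = _ring_geometry(ring_coords)
            rings.append(
                _Ring(tuple(names[i] for i in ring_idx), centroid, normal)
            )
    return _LigandFeatures(
        donors, acceptors, rings, apolar, halogen_donors, anions, cations,
        sulfurs, heavy,
    )


# -- detectors ----------------------------------------------------------------

def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def _hbond_ok(
    d_xyz: np.ndarray,
    h_coords: Sequence[np.ndarray],
    a_xyz: np.ndarray,
    params: GeometryParams,
) -> tuple[bool, Optional[float]]:
    """Angle test at the donor hydrogen; distance-only when no H present."""
    if not h_coords:
        return True, None
    best = max(_angle_at(h, d_xyz, a_xyz) for h in h_coords)
    return best >= params.hbond_angle, best


def detect_hbonds(
    pose: Pose,
    receptor: ReceptorStructure,
    params: GeometryParams = GeometryParams(),
    _residues: Optional[Sequence[Residue]] = None,
) -> list[InteractionRecord]:
    """Hydrogen bonds in both directions (receptor donor <-> ligand donor).

    Distance is reported heavy-to-heavy; the D-H...A angle is enforced only
    when the donor carries explicit hydrogens.
    """
    lig = _ligand_features(pose)
    out = []
    for res in _residues if _residues is not None else receptor.residues:
        feats = _residue_features(res, params)
        for dname, dxyz, hs in feats.donors:
            for aname, axyz in lig.acceptors:
                d = _dist(dxyz, axyz)
                if d <= params.hbond_distance:
                    ok, angle = _hbond_ok(dxyz, hs, axyz, params)
                    if ok:
                        out.append(
                            InteractionRecord(
                                res.rid, "hbond", d, (dname,), (aname,), angle
                            )
                        )
        for aname, axyz in feats.acceptors:
            for dname, dxyz, hs in lig.donors:
                d = _dist(dxyz, axyz)
                if d <= params.hbond_distance:
                    ok, angle = _hbond_ok(dxyz, hs, axyz, params)
                    if ok:
                        out.append(
                            InteractionRecord(
                                res.rid, "hbond", d, (aname,), (dname,), angle
                            )
                        )
    return out


def detect_aromatic(
    pose: Pose,
    receptor: ReceptorStructure,
    params: GeometryParams = GeometryParams(),
    _residues: Optional[Sequence[Residue]] = None,
) -> list[InteractionRecord]:
    """Ring-ring geometry: stacked vs T-shaped by interplanar angle.

    Pairs inside the centroid cutoff whose angle falls in the gap between the
    stacked and T-shaped windows yield no record.
    """
    lig = _ligand_features(pose)
    out = []
    lo, hi = params.pi_tshaped_angle
    for res in _residues if _residues is not None else receptor.residues:
        feats = _residue_features(res, params)
        for rring in feats.rings:
            for lring in lig.rings:
                d = _dist(rring.centroid, lring.centroid)
                if d > params.pi_pi_distance:
                    continue
                angle = _interplanar_angle(rring.normal, lring.normal)
                if angle <= params.pi_stacked_angle:
                    itype = "pi_pi_stacked"
                elif lo <= angle <= hi:
                    itype = "pi_pi_tshaped"
                else:
                    continue
                out.append(
                    InteractionRecord(
                        res.rid, itype, d, rring.atom_names, lring.atom_names,
                        angle,
                    )
                )
    return out


def detect_nonpolar(
    pose: Pose,
    receptor: ReceptorStructure,
    params: GeometryParams = GeometryParams(),
    _residues: Optional[Sequence[Residue]] = None,
) -> list[InteractionRecord]:
    """Alkyl, pi-alkyl and halogen contacts.

    Apolar partners are non-aromatic C bonded only to C/H plus halogens;
    pi-alkyl pairs a ring centroid (either side) with an apolar atom on the
    other side; the halogen type is a ligand Cl/Br/I against receptor O/N/S.
    """
    lig = _ligand_features(pose)
    out = []
    for res in _residues if _residues is not None else receptor.residues:
        feats = _residue_features(res, params)
        for rname, rxyz in feats.apolar:
            for lname, lxyz in lig.apolar:
                d = _dist(rxyz, lxyz)
                if d <= params.alkyl_distance:
                    out.append(
                        InteractionRecord(res.rid, "alkyl", d, (rname,), (lname,))
                    )
        for rring in feats.rings:
            for lname, lxyz in lig.apolar:
                d = _dist(rring.centroid, lxyz)
                if d <= params.pi_alkyl_distance:
                    out.append(
                        InteractionRecord(
                            res.rid, "pi_alkyl", d, rring.atom_names, (lname,)
                        )
                    )
        for lring in lig.rings:
            for rname, rxyz in feats.apolar:
                d = _dist(lring.centroid, rxyz)
                if d <= params.pi_alkyl_distance:
                    out.append(
                        InteractionRecord(
                            res.rid, "pi_alkyl", d, (rname,), lring.atom_names
                        )
                    )
        for rname, rxyz in feats.ons_atoms:
            for lname, lxyz in lig.halogen_donors:
                d = _dist(rxyz, lxyz)
                if d <= params.halogen_distance:
                    out.append(
                        InteractionRecord(res.rid, "halogen", d, (rname,), (lname,))
                    )
    return out


def detect_charged_special(
    pose: Pose,
    receptor: ReceptorStructure,
    params: GeometryParams = GeometryParams(),
    _residues: Optional[Sequence[Residue]] = None,
) -> list[InteractionRecord]:
    """pi-cation, pi-anion and pi-sulfur contacts (both orientations)."""
    lig = _ligand_features(pose)
    out = []
    for res in _residues if _residues is not None else receptor.residues:
        feats = _residue_features(res, params)
        for lring in lig.rings:
            for group, centroid in feats.anion_groups:
                d = _dist(lring.centroid, centroid)
                if d <= params.pi_anion_distance:
                    out.append(
                        InteractionRecord(
                            res.rid, "pi_anion", d, group, lring.atom_names
                        )
                    )
            for group, centroid in feats.cation_groups:
                d = _dist(lring.centroid, centroid)
                if d <= params.pi_cation_distance:
                    out.append(
                        InteractionRecord(
                            res.rid, "pi_cation", d, group, lring.atom_names
                        )
                    )
            for sname, sxyz in feats.sulfurs:
                d = _dist(lring.centroid, sxyz)
                if d <= params.pi_sulfur_distance:
                    out.append(
                        InteractionRecord(
                            res.rid, "pi_sulfur", d, (sname,), lring.atom_names
                        )
                    )
        for rring in feats.rings:
            for lname, lxyz in lig.anions:
                d = _dist(rring.centroid, lxyz)
                if d <= params.pi_anion_distance:
                    out.append(
                        InteractionRecord(
                            res.rid, "pi_anion", d, rring.atom_names, (lname,)
                        )
                    )
            for lname, lxyz in lig.cations:
                d = _dist(rring.centroid, lxyz)
                if d <= params.pi_cation_distance:
                    out.append(
                        InteractionRecord(
                            res.rid, "pi_cation", d, rring.atom_names, (lname,)
                        )
                    )
            for lname, lxyz in lig.sulfurs:
                d = _dist(rring.centroid, lxyz)
                if d <= params.pi_sulfur_distance:
                    out.append(
                        InteractionRecord(
                            res.rid, "pi_sulfur", d, rring.atom_names, (lname,)
                        )
                    )
    return out


def _generic_contacts(
    pose: Pose,
    residues: Sequence[Residue],
    params: GeometryParams,
) -> list[InteractionRecord]:
    lig = _ligand_features(pose)
    if not lig.heavy:
        return []
    lnames = [n for n, _ in lig.heavy]
    lcoords = np.array([c for _, c in lig.heavy])
    out = []
    for res in residues:
        heavy = [(a.name, np.asarray(a.xyz)) for a in res.heavy_atoms()]
        if not heavy:
            continue
        rcoords = np.array([c for _, c in heavy])
        dmat = np.linalg.norm(
            rcoords[:, None, :] - lcoords[None, :, :], axis=-1
        )
        idx = np.unravel_index(np.argmin(dmat), dmat.shape)
        dmin = float(dmat[idx])
        if dmin <= params.generic_distance:
            out.append(
                InteractionRecord(
                    res.rid,
                    "generic_contact",
                    dmin,
                    (heavy[idx[0]][0],),
                    (lnames[idx[1]],),
                )
            )
    return out


def _prefilter_residues(
    pose: Pose, receptor: ReceptorStructure, params: GeometryParams
) -> list[Residue]:
    """Residues with any atom within reach of any ligand atom (k-d tree).

    The search radius pads the largest cutoff by the maximal distance from a
    ring atom to its centroid (both sides), so no centroid-based pair can be
    lost by the atom-level filter.
    """
    ring_pad = 3.0  # > max ring-atom-to-centroid distance (benzene ~1.40 A)
    radius = params.max_cutoff() + 2 * ring_pad
    lig_coords = pose.coords()
    tree = cKDTree(lig_coords)
    kept = []
    for res in receptor.residues:
        coords = res.coords()
        hits = tree.query_ball_point(coords, r=radius)
        if any(len(h) for h in hits):
            kept.append(res)
    return kept


def fingerprint(
    pose: Pose,
    receptor: ReceptorStructure,
    params: GeometryParams = GeometryParams(),
    target_id: str = "",
    accelerated: bool = False,
) -> ContactFingerprint:
    """Union of all typed detectors plus generic contacts for a pose.

    ``accelerated=True`` restricts detectors to k-d-tree-prefiltered residues;
    the result is identical to the all-pairs computation by construction of
    the prefilter radius (and verified against it in the test suite).
    """
    residues = (
        _prefilter_residues(pose, receptor, params)
        if accelerated
        else list(receptor.residues)
    )
    records: list[InteractionRecord] = []
    records += detect_hbonds(pose, receptor, params, _residues=residues)
    records += detect_aromatic(pose, receptor, params, _residues=residues)
    records += detect_nonpolar(pose, receptor, params, _residues=residues)
    records += detect_charged_special(pose, receptor, params, _residues=residues)
    records += _generic_contacts(pose, residues, params)
    return ContactFingerprint(pose.ligand_id, target_id, records)
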