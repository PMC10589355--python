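"""Synthetic test inputs: pockets with planted interactions, ligand libraries.

The pocket generator builds idealized receptor fragments (a serine donor, a
phenylalanine ring, a leucine side chain, a glutamate carboxylate, a lysine
ammonium, a methionine thioether) around probe groups of a synthetic ligand,
one interaction per unit.  Each planted geometry sits strictly inside its
detector's thresholds by a stated margin and each decoy strictly outside, and
units are separated far enough (>= 8.5 A between atoms of different units)
that no cross-unit typed contact is geometrically possible.  The generated
ground truth therefore defines detector correctness: recall must be 1 and
typed false positives 0, independent of floating-point noise.

No physical plausibility beyond geometry is attempted: probe fragments are
disconnected valid small molecules (formaldehyde as an acceptor, benzene as a
pi system, methane as an alkyl probe, a chloride as halogen-bond donor) and
residues carry only the atoms the detectors type.

The library generator emulates the screening inputs: a property table
straddling the scoring ranges, categorical risk/metabolism annotations with a
known level mixture, docking energies, per-target interacting-residue sets
against a synthetic control ligand, and an independently summed expected-score
table that serves as the scoring oracle.

All randomness flows from ``numpy.random.default_rng(seed)`` (PCG64), so every
output is deterministic per seed and stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D

from .interactions import GeometryParams, InteractionRecord
from .structio import Atom, Pose, ReceptorStructure, Residue, ResidueId
from .structio import _pose_from_rdmol

__all__ = [
    "FixtureSpec",
    "LibrarySpec",
    "LibraryTables",
    "PLANTABLE_TYPES",
    "make_ligand_library",
    "make_pocket_fixture",
]

PLANTABLE_TYPES = (
    "hbond",
    "pi_pi_stacked",
    "pi_pi_tshaped",
    "pi_alkyl",
    "alkyl",
    "pi_cation",
    "pi_anion",
    "pi_sulfur",
    "halogen",
)

#: decoy kinds cycled through by the generator: distance decoys for every
#: plantable type plus angle decoys for the two angle-gated detectors
DECOY_KINDS = tuple(f"{t}_far" for t in PLANTABLE_TYPES) + (
    "hbond_angle",
    "pi_pi_angle",
)

_MIN_CROSS_SEPARATION = 8.5  # A, between atoms of different units


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    planted: dict = field(default_factory=dict)  # interaction_type -> count
    decoys: int = 0
    n_residues: Optional[int] = None  # total residues incl. inert fillers
    distance_margin: float = 0.2      # minimal clearance inside thresholds, A
    decoy_distance_margin: float = 0.5
    decoy_angle_margin: float = 15.0

    def __post_init__(self) -> None:
        bad = [t for t in self.planted if t not in PLANTABLE_TYPES]
        if bad:
            raise ValueError(f"unplantable interaction types: {bad}")
        if any(n < 0 for n in self.planted.values()) or self.decoys < 0:
            raise ValueError("counts must be non-negative")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-angle spiral)."""
    if n == 0:
        return np.zeros((0, 3))
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def _frame(u: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u (deterministic via rng)."""
    while True:
        v = rng.normal(size=3)
        e1 = v - np.dot(v, u) * u
        norm = np.linalg.norm(e1)
        if norm > 1e-6:
            break
    e1 /= norm
    e2 = np.cross(u, e1)
    return e1, e2


class _LigandBuilder:
    """Accumulates probe fragments into one RDKit molecule with coordinates."""

    def __init__(self) -> None:
        self.mol = Chem.RWMol()
        self.coords: list[np.ndarray] = []

    def add_fragment(
        self,
        elements: list[str],
        bonds: list[tuple[int, int, Chem.BondType]],
        coords: list[np.ndarray],
    ) -> list[int]:
        offset = self.mol.GetNumAtoms()
        for el in elements:
            self.mol.AddAtom(Chem.Atom(el))
        for i, j, order in bonds:
            self.mol.AddBond(offset + i, offset + j, order)
        self.coords.extend(coords)
        return list(range(offset, offset + len(elements)))

    def finish(self, name: str) -> Chem.Mol:
        mol = self.mol.GetMol()
        Chem.SanitizeMol(mol)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, c in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(*map(float, c)))
        mol.AddConformer(conf)
        mol.SetProp("_Name", name)
        return mol


def _benzene(center: np.ndarray, e1: np.ndarray, e2: np.ndarray):
    """Kekule benzene ring of radius 1.39 A in the plane spanned by e1, e2."""
    coords = []
    for k in range(6):
        ang = np.pi / 3.0 * k
        coords.append(center + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2))
    bonds = []
    for k in range(6):
        order = Chem.BondType.DOUBLE if k % 2 == 0 else Chem.BondType.SINGLE
        bonds.append((k, (k + 1) % 6, order))
    return ["C"] * 6, bonds, coords


def _rotated_ring_frame(
    u: np.ndarray, e1: np.ndarray, e2: np.ndarray, tilt_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane axes of a ring whose normal is u tilted by tilt_deg about e1."""
    t = np.radians(tilt_deg)
    normal = np.cos(t) * u + np.sin(t) * e2
    a1 = e1
    a2 = np.cross(normal, a1)
    a2 /= np.linalg.norm(a2)
    return a1, a2


@dataclass
class _Unit:
    """One planted or decoy interaction: residue atoms + ligand fragment."""

    residue_name: str
    residue_atoms: list[tuple[str, str, np.ndarray]]  # name, element, xyz
    truth: Optional[tuple[str, float, Optional[float], tuple, tuple]] = None
    # (itype, distance, angle, receptor_atom_names, ligand_atom_names)


def _build_unit(
    kind: str,
    u: np.ndarray,
    rng: np.random.Generator,
    builder: _LigandBuilder,
    params: GeometryParams,
    spec: FixtureSpec,
    probe_radius: float,
) -> _Unit:
    """Construct the ligand probe + receptor fragment for one unit.

    ``kind`` is a plantable type (strictly-inside geometry, recorded as ground
    truth) or a decoy kind (strictly-outside geometry, no truth record).
    """
    e1, e2 = _frame(u, rng)
    p = probe_radius * u
    m = spec.distance_margin
    dm = spec.decoy_distance_margin
    am = spec.decoy_angle_margin
    U = lambda lo, hi: float(rng.uniform(lo, hi))

    base = kind[:-4] if kind.endswith("_far") else kind

    if kind in ("hbond", "hbond_far", "hbond_angle"):
        # ligand formaldehyde acceptor; receptor serine O-H donor
        ids = builder.add_fragment(
            ["O", "C"],
            [(0, 1, Chem.BondType.DOUBLE)],
            [p, p - 1.22 * u],
        )
        lig_name = f"O{ids[0] + 1}"
        if kind == "hbond":
            d = U(params.hbond_distance - 0.8, params.hbond_distance - m)
            tilt = np.radians(U(0.0, 15.0))
        elif kind == "hbond_far":
            d = params.hbond_distance + dm
            tilt = 0.0
        else:  # hbond_angle: inside distance, angle far below threshold
            d = 3.0
            tilt = np.radians(90.0)
        og = p + d * u
        hg = og + 0.96 * (np.cos(tilt) * (-u) + np.sin(tilt) * e1)
        cb = og + 1.43 * u
        atoms = [("CB", "C", cb), ("OG", "O", og), ("HG", "H", hg)]
        truth = None
        if kind == "hbond":
            angle = _planted_angle(hg, og, p)
            truth = ("hbond", d, angle, ("OG",), (lig_name,))
        return _Unit("SER", atoms, truth)

    if base in ("pi_pi_stacked", "pi_pi_tshaped", "pi_pi_angle"):
        a1, a2 = e1, e2
        els, bonds, coords = _benzene(p, a1, a2)
        ids = builder.add_fragment(els, bonds, coords)
        lig_names = tuple(f"C{i + 1}" for i in ids)
        if kind == "pi_pi_stacked":
            d = U(3.4, 4.2)
            tilt = U(0.0, params.pi_stacked_angle - 10.0)
        elif kind == "pi_pi_tshaped":
            lo, hi = params.pi_tshaped_angle
            d = U(4.0, params.pi_pi_distance - 0.3)
            tilt = U(lo + 10.0, hi)
        elif kind == "pi_pi_angle":
            d = U(4.0, 5.0)
            tilt = (params.pi_stacked_angle + params.pi_tshaped_angle[0]) / 2.0
        else:  # pi_pi_stacked_far / pi_pi_tshaped_far
            d = params.pi_pi_distance + dm
            tilt = 0.0 if "stacked" in kind else 80.0
        center = p + d * u
        r1, r2 = _rotated_ring_frame(u, e1, e2, tilt)
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        atoms = []
        for name, k in zip(ring_names, range(6)):
            ang = np.pi / 3.0 * k
            atoms.append(
                (name, "C", center + 1.39 * (np.cos(ang) * r1 + np.sin(ang) * r2))
            )
        atoms.append(("CB", "C", center + 2.2 * u))
        truth = None
        if kind in ("pi_pi_stacked", "pi_pi_tshaped"):
            truth = (kind, d, tilt, ring_names, lig_names)
        return _Unit("PHE", atoms, truth)

    if base == "pi_alkyl":
        ids = builder.add_fragment(["C"], [], [p])
        lig_name = f"C{ids[0] + 1}"
        d = (
            U(3.8, params.pi_alkyl_distance - m)
            if kind == "pi_alkyl"
            else params.pi_alkyl_distance + dm
        )
        center = p + d * u
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        atoms = []
        for name, k in zip(ring_names, range(6)):
            ang = np.pi / 3.0 * k
            atoms.append(
                (name, "C", center + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2))
            )
        atoms.append(("CB", "C", center + 2.2 * u))
        truth = (
            ("pi_alkyl", d, None, ring_names, (lig_name,))
            if kind == "pi_alkyl"
            else None
        )
        return _Unit("PHE", atoms, truth)

    if base == "alkyl":
        ids = builder.add_fragment(["C"], [], [p])
        lig_name = f"C{ids[0] + 1}"
        d = (
            U(3.4, params.alkyl_distance - m)
            if kind == "alkyl"
            else params.alkyl_distance + dm
        )
        cd1 = p + d * u
        cg = cd1 + 1.54 * u
        cd2 = cg + 1.54 * (0.5 * u + 0.866 * e1)
        cb = cg + 1.54 * (0.5 * u - 0.866 * e1)
        atoms = [
            ("CB", "C", cb),
            ("CG", "C", cg),
            ("CD1", "C", cd1),
            ("CD2", "C", cd2),
        ]
        truth = (
            ("alkyl", d, None, ("CD1",), (lig_name,)) if kind == "alkyl" else None
        )
        return _Unit("LEU", atoms, truth)

    if base == "pi_cation":
        els, bonds, coords = _benzene(p, e1, e2)
        ids = builder.add_fragment(els, bonds, coords)
        lig_names = tuple(f"C{i + 1}" for i in ids)
        d = (
            U(3.5, params.pi_cation_distance - m)
            if kind == "pi_cation"
            else params.pi_cation_distance + dm
        )
        nz = p + d * u
        ce = nz + 1.49 * u
        cd = ce + 1.54 * u
        cg = cd + 1.54 * u
        cb = cg + 1.54 * u
        atoms = [
            ("CB", "C", cb), ("CG", "C", cg), ("CD", "C", cd),
            ("CE", "C", ce), ("NZ", "N", nz),
        ]
        truth = (
            ("pi_cation", d, None, ("NZ",), lig_names)
            if kind == "pi_cation"
            else None
        )
        return _Unit("LYS", atoms, truth)

    if base == "pi_anion":
        els, bonds, coords = _benzene(p, e1, e2)
        ids = builder.add_fragment(els, bonds, coords)
        lig_names = tuple(f"C{i + 1}" for i in ids)
        d = (
            U(3.5, params.pi_anion_distance - m)
            if kind == "pi_anion"
            else params.pi_anion_distance + dm
        )
        mid = p + d * u
        oe1 = mid + 1.1 * e1
        oe2 = mid - 1.1 * e1
        cd = mid + 0.65 * u
        cg = cd + 1.52 * u
        cb = cg + 1.54 * u
        atoms = [
            ("CB", "C", cb), ("CG", "C", cg), ("CD", "C", cd),
            ("OE1", "O", oe1), ("OE2", "O", oe2),
        ]
        truth = (
            ("pi_anion", d, None, ("OE1", "OE2"), lig_names)
            if kind == "pi_anion"
            else None
        )
        return _Unit("GLU", atoms, truth)

    if base == "pi_sulfur":
        els, bonds, coords = _benzene(p, e1, e2)
        ids = builder.add_fragment(els, bonds, coords)
        lig_names = tuple(f"C{i + 1}" for i in ids)
        d = (
            U(4.0, params.pi_sulfur_distance - m)
            if kind == "pi_sulfur"
            else params.pi_sulfur_distance + dm
        )
        sd = p + d * u
        cg = sd + 1.8 * (0.64 * u + 0.77 * e1)
        ce = sd + 1.8 * (0.64 * u - 0.77 * e1)
        cb = cg + 1.53 * u
        atoms = [
            ("CB", "C", cb), ("CG", "C", cg), ("SD", "S", sd), ("CE", "C", ce),
        ]
        truth = (
            ("pi_sulfur", d, None, ("SD",), lig_names)
            if kind == "pi_sulfur"
            else None
        )
        return _Unit("MET", atoms, truth)

    if base == "halogen":
        ids = builder.add_fragment(["Cl"], [], [p])
        lig_name = f"Cl{ids[0] + 1}"
        d = (
            U(3.0, params.halogen_distance - m)
            if kind == "halogen"
            else params.halogen_distance + dm
        )
        og = p + d * u
        cb = og + 1.43 * u
        atoms = [("CB", "C", cb), ("OG", "O", og)]
        truth = (
            ("halogen", d, None, ("OG",), (lig_name,))
            if kind == "halogen"
            else None
        )
        return _Unit("SER", atoms, truth)

    raise ValueError(f"unknown unit kind {kind!r}")


def _planted_angle(h: np.ndarray, d: np.ndarray, a: np.ndarray) -> float:
    v1, v2 = d - h, a - h
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def make_pocket_fixture(
    spec: FixtureSpec, params: GeometryParams = GeometryParams()
) -> tuple[ReceptorStructure, Pose, list[InteractionRecord]]:
    """Deterministic toy pocket with planted interactions and decoys.

    Returns the receptor, the ligand pose (with RDKit topology) and the
    ground-truth record list (exactly the planted interactions).
    """
    kinds: list[str] = []
    for itype in PLANTABLE_TYPES:  # fixed vocabulary order for determinism
        kinds.extend([itype] * int(spec.planted.get(itype, 0)))
    for k in range(spec.decoys):
        kinds.append(DECOY_KINDS[k % len(DECOY_KINDS)])

    n_units = len(kinds)
    n_residues = spec.n_residues if spec.n_residues is not None else n_units
    if n_residues < n_units:
        raise ValueError(
            f"{n_units} planted/decoy units exceed n_residues={n_residues}"
        )

    probe_radius = 30.0
    for attempt in range(6):
        rng = np.random.default_rng(spec.seed)
        rot = _random_rotation(rng)
        dirs = _fibonacci_sphere(n_units) @ rot.T
        builder = _LigandBuilder()
        units: list[_Unit] = []
        unit_atom_coords: list[np.ndarray] = []
        for kind, u in zip(kinds, dirs):
            start = len(builder.coords)
            unit = _build_unit(kind, u, rng, builder, params, spec, probe_radius)
            probe_coords = builder.coords[start:]
            unit_atom_coords.append(
                np.array(
                    [c for _, _, c in unit.residue_atoms] + list(probe_coords)
                )
            )
            units.append(unit)
        if _units_separated(unit_atom_coords):
            break
        probe_radius += 5.0
    else:
        raise RuntimeError("could not separate fixture units; too many planted")

    residues: list[Residue] = []
    truth: list[InteractionRecord] = []
    for i, unit in enumerate(units, start=1):
        rid = ResidueId("A", str(i), unit.residue_name)
        residues.append(
            Residue(
                rid,
                [Atom(n, el, tuple(np.round(c, 3))) for n, el, c in unit.residue_atoms],
            )
        )
        if unit.truth is not None:
            itype, d, angle, ratoms, latoms = unit.truth
            truth.append(InteractionRecord(rid, itype, d, ratoms, latoms, angle))

    # inert fillers far outside every cutoff
    n_fillers = n_residues - n_units
    if n_fillers:
        filler_dirs = _fibonacci_sphere(n_fillers) @ _random_rotation(rng).T
        for j, u in enumerate(filler_dirs, start=n_units + 1):
            c = 60.0 * u
            residues.append(
                Residue(
                    ResidueId("A", str(j), "GLY"),
                    [
                        Atom("N", "N", tuple(np.round(c, 3))),
                        Atom("CA", "C", tuple(np.round(c + np.array([1.46, 0, 0]), 3))),
                        Atom("C", "C", tuple(np.round(c + np.array([2.4, 1.1, 0]), 3))),
                        Atom("O", "O", tuple(np.round(c + np.array([2.4, 2.33, 0]), 3))),
                    ],
                )
            )

    receptor = ReceptorStructure(residues)
    if builder.mol.GetNumAtoms() == 0:
        # degenerate empty plant: a single distant methane keeps the pose valid
        builder.add_fragment(["C"], [], [np.array([500.0, 500.0, 500.0])])
    mol = builder.finish(f"synthetic-{spec.seed}")
    pose = _pose_from_rdmol(mol, f"synthetic-{spec.seed}", None)
    return receptor, pose, truth


def _units_separated(unit_coords: list[np.ndarray]) -> bool:
    for i in range(len(unit_coords)):
        for j in range(i + 1, len(unit_coords)):
            diff = unit_coords[i][:, None, :] - unit_coords[j][None, :, :]
            if float(np.min(np.linalg.norm(diff, axis=-1))) < _MIN_CROSS_SEPARATION:
                return False
    return True


# -- ligand library -----------------------------------------------------------

@dataclass(frozen=True)
class LibrarySpec:
    """Controlled-distribution screening library.

    ``in_range_fractions`` gives, per scored property, the probability that a
    sampled value falls inside its scoring range; level mixtures give the
    categorical probabilities (high, medium, low) for the annotations.
    """

    seed: int
    n_ligands: int = 40
    targets: tuple[str, ...] = ("BCL2", "GPER")
    in_range_fractions: dict = field(
        default_factory=lambda: {"mw": 0.6, "logp": 0.6, "hba": 0.6, "hbd": 0.6}
    )
    risk_mixture: tuple[float, float, float] = (0.2, 0.3, 0.5)
    metabolism_mixture: tuple[float, float, float] = (0.2, 0.5, 0.3)
    energy_range: tuple[float, float] = (-12.0, -5.0)
    n_control_residues: int = 13

    def __post_init__(self) -> None:
        if self.n_ligands < 0:
            raise ValueError("n_ligands must be >= 0")
        for k, f in self.in_range_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {k} outside [0,1]")


@dataclass
class LibraryTables:
    properties: pd.DataFrame
    risk: pd.DataFrame
    metabolism: pd.DataFrame
    energies: pd.DataFrame
    controls: dict           # target -> frozenset of residue labels
    fingerprints: dict       # target -> {ligand_id -> frozenset}
    expected: pd.DataFrame   # independent expected-score oracle


# scoring ranges restated independently of the scoring module (oracle)
_RANGES = {"mw": (200.0, 500.0), "logp": (2.0, 5.0), "hba": (5, 10), "hbd": (2, 5)}
_BELOW = {"mw": (120.0, 195.0), "logp": (-1.0, 1.8), "hba": (0, 4), "hbd": (0, 1)}
_ABOVE = {"mw": (505.0, 750.0), "logp": (5.2, 8.0), "hba": (11, 15), "hbd": (6, 9)}
_LEVELS = ("high", "medium", "low")
_ORACLE_RISK = {"high": 0, "medium": 10, "low": 20}
_ORACLE_PEN = {"high": -20, "medium": -15, "low": -10}


def make_ligand_library(spec: LibrarySpec) -> LibraryTables:
    """Generate all screening-stage inputs plus the expected-score oracle."""
    rng = np.random.default_rng(spec.seed)
    targets = tuple(sorted(spec.targets))
    ids = [f"L{i:04d}" for i in range(spec.n_ligands)]

    controls = {
        t: frozenset(f"{t}:R{j + 1}" for j in range(spec.n_control_residues))
        for t in targets
    }

    prop_rows, risk_rows, met_rows, energy_rows, expected_rows = [], [], [], [], []
    fingerprints: dict = {t: {} for t in targets}

    for lid in ids:
        values: dict = {}
        for key in ("mw", "logp", "hba", "hbd"):
            f = spec.in_range_fractions.get(key, 0.6)
            if rng.random() < f:
                lo, hi = _RANGES[key]
            else:
                lo, hi = _BELOW[key] if rng.random() < 0.5 else _ABOVE[key]
            if key in ("hba", "hbd"):
                values[key] = int(rng.integers(lo, hi + 1))
            else:
                values[key] = float(rng.uniform(lo, hi))
        values["tpsa"] = float(rng.uniform(20.0, 140.0))
        prop_rows.append({"ligand_id": lid, **{
            "mw": values["mw"], "logp": values["logp"], "hbd": values["hbd"],
            "hba": values["hba"], "tpsa": values["tpsa"],
        }})

        risk_levels = {
            e: _LEVELS[rng.choice(3, p=spec.risk_mixture)]
            for e in ("mutagenicity", "teratogenicity", "tumorigenicity", "irritability")
        }
        risk_rows.append({"ligand_id": lid, **risk_levels})
        met_level = _LEVELS[rng.choice(3, p=spec.metabolism_mixture)]
        met_rows.append({"ligand_id": lid, "predisposition": met_level})

        # oracle point terms, computed from the sampled values directly
        lip = 0
        for key in ("mw", "logp", "hba", "hbd"):
            lo, hi = _RANGES[key]
            if lo <= values[key] <= hi:
                lip += 10
        tox = sum(_ORACLE_RISK[lvl] for lvl in risk_levels.values())
        pen = _ORACLE_PEN[met_level]

        expected = 0.0
        per_target: dict = {}
        for t in targets:
            energy = float(rng.uniform(*spec.energy_range))
            energy_rows.append(
                {"ligand_id": lid, "target_id": t, "binding_energy": energy}
            )
            control = sorted(controls[t])
            n_shared = int(rng.integers(0, spec.n_control_residues + 1))
            shared = list(rng.choice(control, size=n_shared, replace=False))
            n_extra = int(rng.integers(0, 4))
            extra = [f"{t}:X{lid}{k}" for k in range(n_extra)]
            fingerprints[t][lid] = frozenset(shared + extra)
            sim = 100.0 * n_shared / spec.n_control_residues
            abs_be = abs(energy)
            per_target[t] = (abs_be, sim)
            expected += abs_be + sim
        expected += lip + tox + pen

        row = {"ligand_id": lid, "lipinski_points": lip, "tox_points": tox,
               "metabolism_penalty": pen, "expected_composite": expected}
        for t in targets:
            row[f"abs_be_{t}"] = per_target[t][0]
            row[f"sim_bm_{t}"] = per_target[t][1]
        expected_rows.append(row)

    return LibraryTables(
        properties=pd.DataFrame(
            prop_rows, columns=["ligand_id", "mw", "logp", "hbd", "hba", "tpsa"]
        ),
        risk=pd.DataFrame(
            risk_rows,
            columns=["ligand_id", "mutagenicity", "teratogenicity",
                     "tumorigenicity", "irritability"],
        ),
        metabolism=pd.DataFrame(met_rows, columns=["ligand_id", "predisposition"]),
        energies=pd.DataFrame(
            energy_rows, columns=["ligand_id", "target_id", "binding_energy"]
        ),
        controls=controls,
        fingerprints=fingerprints,
        expected=pd.DataFrame(expected_rows),
    )
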