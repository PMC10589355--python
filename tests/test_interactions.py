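"""Geometric interaction detectors on constructed and planted geometries."""

import numpy as np
import pytest
from rdkit import Chem

from dualvs.interactions import (
    GeometryParams,
    detect_aromatic,
    detect_charged_special,
    detect_hbonds,
    detect_nonpolar,
    fingerprint,
)
from dualvs.structio import Atom, Pose, ReceptorStructure
from dualvs.synthetic import FixtureSpec, make_pocket_fixture

from conftest import (
    benzene_fragment,
    make_pose_from_fragments,
    make_residue,
    random_rotation,
    receptor_phe_ring,
    rigid_transform,
)


def formaldehyde_at(o_pos):
    """Ligand C=O acceptor fragment with the oxygen at o_pos."""
    o = np.asarray(o_pos, dtype=float)
    return (["O", "C"], [(0, 1, Chem.BondType.DOUBLE)], [o, o + [0.0, 0.0, -1.22]])


def serine_donor(og_pos, h_toward, with_h=True, number="1"):
    """SER with OG at og_pos and HG 0.96 A toward h_toward."""
    og = np.asarray(og_pos, dtype=float)
    direction = np.asarray(h_toward, dtype=float) - og
    direction = direction / np.linalg.norm(direction)
    atoms = [("CB", "C", tuple(og - 1.43 * direction)), ("OG", "O", tuple(og))]
    if with_h:
        atoms.append(("HG", "H", tuple(og + 0.96 * direction)))
    return make_residue("SER", atoms, number=number)


class TestHbonds:
    def test_pair_inside_thresholds_detected(self, params):
        pose = make_pose_from_fragments([formaldehyde_at((0, 0, 0))])
        receptor = ReceptorStructure([serine_donor((0, 0, 2.9), (0, 0, 0))])
        records = detect_hbonds(pose, receptor, params)
        assert [r.interaction_type for r in records] == ["hbond"]
        assert records[0].distance == pytest.approx(2.9)
        assert records[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_beyond_cutoff_not_detected(self, params):
        pose = make_pose_from_fragments([formaldehyde_at((0, 0, 0))])
        receptor = ReceptorStructure([serine_donor((0, 0, 5.0), (0, 0, 0))])
        assert detect_hbonds(pose, receptor, params) == []

    def test_boundary_is_inclusive(self, params):
        pose = make_pose_from_fragments([formaldehyde_at((0, 0, 0))])
        receptor = ReceptorStructure(
            [serine_donor((0, 0, params.hbond_distance), (0, 0, 0))]
        )
        records = detect_hbonds(pose, receptor, params)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(params.hbond_distance)

    def test_bad_angle_rejected_when_h_explicit(self, params):
        pose = make_pose_from_fragments([formaldehyde_at((0, 0, 0))])
        # H points perpendicular to the donor-acceptor axis: angle ~72 deg
        receptor = ReceptorStructure([serine_donor((0, 0, 3.0), (5.0, 0, 3.0))])
        assert detect_hbonds(pose, receptor, params) == []

    def test_distance_only_fallback_without_h(self, params):
        pose = make_pose_from_fragments([formaldehyde_at((0, 0, 0))])
        receptor = ReceptorStructure(
            [serine_donor((0, 0, 3.0), (5.0, 0, 3.0), with_h=False)]
        )
        records = detect_hbonds(pose, receptor, params)
        assert len(records) == 1
        assert records[0].angle is None


class TestAromatic:
    def test_parallel_rings_stacked(self, params):
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure([receptor_phe_ring((0, 0, 3.8), (0, 0, 1))])
        records = detect_aromatic(pose, receptor, params)
        assert [r.interaction_type for r in records] == ["pi_pi_stacked"]
        assert records[0].distance == pytest.approx(3.8)
        assert records[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_rings_tshaped(self, params):
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure([receptor_phe_ring((0, 0, 5.0), (1, 0, 0))])
        records = detect_aromatic(pose, receptor, params)
        assert [r.interaction_type for r in records] == ["pi_pi_tshaped"]
        assert records[0].angle == pytest.approx(90.0, abs=1e-6)

    def test_distant_rings_ignored(self, params):
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure([receptor_phe_ring((0, 0, 8.0), (0, 0, 1))])
        assert detect_aromatic(pose, receptor, params) == []

    def test_gap_angle_yields_no_record(self, params):
        normal = (np.sin(np.radians(45.0)), 0.0, np.cos(np.radians(45.0)))
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure([receptor_phe_ring((0, 0, 4.5), normal)])
        assert detect_aromatic(pose, receptor, params) == []


class TestNonpolar:
    def test_methyl_near_leucine_is_alkyl(self, params):
        pose = make_pose_from_fragments([(["C"], [], [(0.0, 0.0, 0.0)])])
        receptor = ReceptorStructure(
            [
                make_residue(
                    "LEU",
                    [
                        ("CD1", "C", (0, 0, 4.0)),
                        ("CG", "C", (0, 0, 5.54)),
                        ("CB", "C", (0, 0, 7.08)),
                    ],
                )
            ]
        )
        records = detect_nonpolar(pose, receptor, params)
        types = sorted(r.interaction_type for r in records)
        assert types == ["alkyl"]
        assert records[0].distance == pytest.approx(4.0)

    def test_ring_centroid_near_carbon_is_pi_alkyl(self, params):
        pose = make_pose_from_fragments([(["C"], [], [(0.0, 0.0, 0.0)])])
        receptor = ReceptorStructure(
            [receptor_phe_ring((0, 0, 4.8), (0, 0, 1), with_cb=False)]
        )
        records = detect_nonpolar(pose, receptor, params)
        assert [r.interaction_type for r in records] == ["pi_alkyl"]
        assert records[0].distance == pytest.approx(4.8)

    def test_aromatic_carbons_are_not_alkyl_partners(self, params):
        # two close rings must classify via the pi channel only
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure(
            [receptor_phe_ring((0, 0, 3.8), (0, 0, 1), with_cb=False)]
        )
        assert detect_nonpolar(pose, receptor, params) == []

    def test_distant_chlorine_ignored(self, params):
        pose = make_pose_from_fragments([(["Cl"], [], [(0.0, 0.0, 0.0)])])
        receptor = ReceptorStructure([serine_donor((0, 0, 6.5), (0, 0, 0))])
        assert detect_nonpolar(pose, receptor, params) == []

    def test_chlorine_near_hydroxyl_is_halogen_bond(self, params):
        pose = make_pose_from_fragments([(["Cl"], [], [(0.0, 0.0, 0.0)])])
        receptor = ReceptorStructure(
            [serine_donor((0, 0, 4.0), (0, 0, 0), with_h=False)]
        )
        records = detect_nonpolar(pose, receptor, params)
        assert [r.interaction_type for r in records] == ["halogen"]


class TestChargedSpecial:
    def test_ring_near_glutamate_is_pi_anion(self, params):
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure(
            [
                make_residue(
                    "GLU",
                    [
                        ("OE1", "O", (1.1, 0, 4.5)),
                        ("OE2", "O", (-1.1, 0, 4.5)),
                        ("CD", "C", (0, 0, 5.15)),
                        ("CG", "C", (0, 0, 6.67)),
                    ],
                )
            ]
        )
        records = [
            r
            for r in detect_charged_special(pose, receptor, params)
            if r.interaction_type == "pi_anion"
        ]
        assert len(records) == 1
        assert records[0].distance == pytest.approx(4.5)

    def test_ring_near_methionine_sulfur_is_pi_sulfur(self, params):
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure(
            [
                make_residue(
                    "MET",
                    [
                        ("SD", "S", (0, 0, 5.2)),
                        ("CG", "C", (1.4, 0, 6.4)),
                        ("CE", "C", (-1.4, 0, 6.4)),
                    ],
                )
            ]
        )
        records = detect_charged_special(pose, receptor, params)
        assert [r.interaction_type for r in records] == ["pi_sulfur"]
        assert records[0].distance == pytest.approx(5.2)

    def test_neutral_residue_yields_no_charged_record(self, params):
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure(
            [make_residue("ALA", [("CB", "C", (0, 0, 4.0))])]
        )
        assert detect_charged_special(pose, receptor, params) == []

    def test_his_cationic_flag(self):
        his = make_residue(
            "HIS",
            [
                ("ND1", "N", (0.7, 0, 4.2)),
                ("NE2", "N", (-0.7, 0, 4.2)),
            ],
        )
        pose = make_pose_from_fragments([benzene_fragment((0, 0, 0))])
        receptor = ReceptorStructure([his])
        neutral = detect_charged_special(pose, receptor, GeometryParams())
        charged = detect_charged_special(
            pose, receptor, GeometryParams(his_cationic=True)
        )
        assert [r.interaction_type for r in neutral] == []
        assert "pi_cation" in {r.interaction_type for r in charged}


class TestFingerprint:
    def test_planted_residue_set_size(self):
        receptor, pose, truth = make_pocket_fixture(
            FixtureSpec(seed=1, planted={"hbond": 1, "pi_pi_stacked": 1, "alkyl": 1})
        )
        fp = fingerprint(pose, receptor)
        assert len(fp.residues) == 3
        assert fp.typed_pairs == {(t.residue, t.interaction_type) for t in truth}

    def test_translated_pose_has_empty_fingerprint(self):
        receptor, pose, _ = make_pocket_fixture(
            FixtureSpec(seed=1, planted={"hbond": 2})
        )
        far = Pose(
            pose.ligand_id,
            [
                Atom(a.name, a.element, (a.xyz[0] + 500.0, a.xyz[1], a.xyz[2]))
                for a in pose.atoms
            ],
            topology=pose.topology,
        )
        assert fingerprint(far, receptor).residues == frozenset()

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        receptor, pose, _ = make_pocket_fixture(
            FixtureSpec(
                seed=seed,
                planted={"hbond": 2, "pi_pi_tshaped": 1, "pi_anion": 1, "alkyl": 1},
            )
        )
        base = fingerprint(pose, receptor)
        rng = np.random.default_rng(seed + 1000)
        rot = random_rotation(rng)
        trans = rng.uniform(-30, 30, size=3)
        receptor2, pose2 = rigid_transform(receptor, pose, rot, trans)
        moved = fingerprint(pose2, receptor2)
        key = lambda fp: sorted(
            (r.residue, r.interaction_type, round(r.distance, 6)) for r in fp.records
        )
        assert key(base) == key(moved)

    def test_monotone_in_distance_cutoffs(self):
        receptor, pose, _ = make_pocket_fixture(
            FixtureSpec(
                seed=4,
                planted={"hbond": 2, "pi_pi_stacked": 1, "pi_sulfur": 1},
                decoys=5,
            )
        )
        small = fingerprint(pose, receptor, GeometryParams())
        enlarged = GeometryParams(
            hbond_distance=4.5, pi_pi_distance=7.0, pi_alkyl_distance=6.5,
            pi_cation_distance=6.5, pi_anion_distance=6.5, pi_sulfur_distance=7.0,
            alkyl_distance=6.0, halogen_distance=6.0, generic_distance=5.5,
        )
        big = fingerprint(pose, receptor, enlarged)
        assert small.typed_pairs <= big.typed_pairs
        assert small.residues <= big.residues

    def test_accelerated_matches_all_pairs(self):
        receptor, pose, _ = make_pocket_fixture(
            FixtureSpec(seed=9, planted={"hbond": 3, "pi_alkyl": 2}, decoys=6)
        )
        brute = fingerprint(pose, receptor, accelerated=False)
        fast = fingerprint(pose, receptor, accelerated=True)
        assert sorted(map(repr, brute.records)) == sorted(map(repr, fast.records))
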