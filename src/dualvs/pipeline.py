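"""End-to-end orchestration: fingerprint -> similarity -> scoring -> ranking.

A run is described by a :class:`RunConfig` (usually loaded from YAML): one or
more targets, each with a receptor, a control pose (the reference ligand whose
interacting residues anchor %similarityBM) and a docked-pose file, plus the
shared energy/property/annotation tables.  Outputs are deterministic: the same
config and inputs reproduce byte-identical CSVs, and the written manifest
(config echo, library versions, seed) suffices to reproduce a run.

Missing-annotation policy: a ligand present in the poses but absent from an
annotation table is scored with the affected component at its WORST value
(0 toxicity points, -20 metabolism penalty, 0 drug-likeness points, |BE| = 0)
and flagged in the ``flags`` column, so the ranking stays total over the
library instead of silently dropping ligands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .chem import PropertySet
from .interactions import ContactFingerprint, GeometryParams, fingerprint
from .scoring import (
    MetabolismAnnotation,
    RiskAnnotation,
    ScoreComponents,
    VSRecord,
    composite_score,
    lipinski_points,
    metabolism_penalty,
    normalize_energy_terms,
    rank_library,
    read_metabolism_csv,
    read_risk_csv,
    scores_frame,
    similarity_bm,
    tox_points,
)
from .structio import EnergyTable, read_energy_table, read_poses, read_receptor

logger = logging.getLogger("dualvs")

__all__ = [
    "RunConfig",
    "TargetConfig",
    "report_contacts",
    "run_pipeline",
    "score_annotated_library",
]


@dataclass
class TargetConfig:
    id: str
    receptor: Path
    control_pose: Path
    poses: Path


@dataclass
class RunConfig:
    targets: list[TargetConfig]
    energies: Optional[Path] = None
    properties: Optional[Path] = None
    risk: Optional[Path] = None
    metabolism: Optional[Path] = None
    output_dir: Path = Path("dualvs_out")
    geometry: GeometryParams = field(default_factory=GeometryParams)
    similarity_interpretation: str = "control_fraction"
    normalize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("config must declare at least one target")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def resolve(p):
            return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

        targets = [
            TargetConfig(
                id=t["id"],
                receptor=resolve(t["receptor"]),
                control_pose=resolve(t["control_pose"]),
                poses=resolve(t["poses"]),
            )
            for t in raw.get("targets", [])
        ]
        geometry = GeometryParams.from_dict(raw.get("geometry", {})) if raw.get(
            "geometry"
        ) else GeometryParams()
        return cls(
            targets=targets,
            energies=resolve(raw.get("energies")),
            properties=resolve(raw.get("properties")),
            risk=resolve(raw.get("risk")),
            metabolism=resolve(raw.get("metabolism")),
            output_dir=resolve(raw.get("output_dir", "dualvs_out")),
            geometry=geometry,
            similarity_interpretation=raw.get(
                "similarity_interpretation", "control_fraction"
            ),
            normalize=bool(raw.get("normalize", False)),
            seed=int(raw.get("seed", 0)),
        )

    def validate_paths(self) -> None:
        for t in self.targets:
            for p, what in ((t.receptor, "receptor"), (t.control_pose, "control pose"),
                            (t.poses, "poses")):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"target {t.id}: missing {what} file {p}"
                    )
        for p in (self.energies, self.properties, self.risk, self.metabolism):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"missing input file {p}")


def score_annotated_library(
    properties: pd.DataFrame,
    risk: dict[str, RiskAnnotation],
    metabolism: dict[str, MetabolismAnnotation],
    energies: EnergyTable,
    fingerprints: dict[str, dict],
    controls: dict[str, frozenset],
    interpretation: str = "control_fraction",
    normalize: bool = False,
) -> list[VSRecord]:
    """Score and rank a library from tables and per-target residue sets.

    ``fingerprints[target][ligand]`` is an interacting-residue set (or a
    :class:`ContactFingerprint`); ``controls[target]`` the control ligand's
    set.  Missing annotations apply the worst-value-and-flag policy.
    """
    targets = sorted(controls)
    props_by_id = {}
    if properties is not None and len(properties):
        for row in properties.itertuples(index=False):
            props_by_id[str(row.ligand_id)] = PropertySet(
                molecular_weight=float(row.mw),
                log_p=float(row.logp),
                hbd=int(row.hbd),
                hba=int(row.hba),
                tpsa=float(row.tpsa),
            )

    ligand_ids = sorted({lid for t in targets for lid in fingerprints.get(t, {})})
    records = []
    for lid in ligand_ids:
        flags = []
        if lid in props_by_id:
            lip = lipinski_points(props_by_id[lid])
        else:
            lip = 0
            flags.append("missing_properties")
        if lid in risk:
            tox = tox_points(risk[lid])
        else:
            tox = 0
            flags.append("missing_risk")
        if lid in metabolism:
            pen = metabolism_penalty(metabolism[lid])
        else:
            pen = -20
            flags.append("missing_metabolism")

        components = {}
        for t in targets:
            fp = fingerprints.get(t, {}).get(lid)
            if fp is None:
                flags.append(f"missing_pose_{t}")
                components[t] = ScoreComponents(0.0, 0.0, lip, tox, pen)
                continue
            sim = similarity_bm(fp, controls[t], interpretation=interpretation)
            energy = energies.get(lid, t)
            if energy is None:
                flags.append(f"missing_energy_{t}")
                abs_be = 0.0
            else:
                abs_be = abs(energy)
            components[t] = ScoreComponents(abs_be, sim, lip, tox, pen)
        rec = VSRecord(lid, components, flags=tuple(flags))
        rec.composite = composite_score([components[t] for t in targets])
        records.append(rec)
    if normalize:
        normalize_energy_terms(records)
    return rank_library(records)


def report_contacts(fp: ContactFingerprint) -> pd.DataFrame:
    """2D contact summary: one row per residue, types and minimum distance."""
    rows: dict = {}
    for r in fp.records:
        entry = rows.setdefault(
            r.residue, {"types": set(), "min_distance": r.distance}
        )
        entry["types"].add(r.interaction_type)
        entry["min_distance"] = min(entry["min_distance"], r.distance)

    def sort_key(rid):
        digits = "".join(c for c in rid.number if c.isdigit())
        return (rid.chain, int(digits) if digits else 0, rid.number)

    out = []
    for rid in sorted(rows, key=sort_key):
        out.append(
            {
                "residue": rid.label,
                "chain": rid.chain,
                "number": rid.number,
                "types": ",".join(sorted(rows[rid]["types"])),
                "min_distance": rows[rid]["min_distance"],
            }
        )
    return pd.DataFrame(
        out, columns=["residue", "chain", "number", "types", "min_distance"]
    )


def _library_versions() -> dict:
    import gemmi
    import numpy
    import rdkit
    import scipy

    return {
        "dualvs": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "rdkit": rdkit.__version__,
        "gemmi": gemmi.__version__,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen; returns a dict of written output paths."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fpdir = out / "fingerprints"
    fpdir.mkdir(exist_ok=True)

    energies = (
        read_energy_table(config.energies) if config.energies else EnergyTable()
    )
    properties = pd.read_csv(config.properties, dtype={"ligand_id": str}) if config.properties else None
    risk = read_risk_csv(config.risk) if config.risk else {}
    metabolism = read_metabolism_csv(config.metabolism) if config.metabolism else {}

    controls: dict = {}
    fingerprints: dict = {}
    for t in config.targets:
        receptor = read_receptor(t.receptor)
        control_poses = read_poses(t.control_pose, energies, t.id)
        if not control_poses:
            raise ValueError(f"target {t.id}: control pose file {t.control_pose} is empty")
        control_fp = fingerprint(
            control_poses[0], receptor, config.geometry, target_id=t.id,
            accelerated=True,
        )
        if not control_fp.residues:
            raise ValueError(
                f"target {t.id}: control ligand makes no contacts; "
                "%similarityBM undefined"
            )
        controls[t.id] = control_fp.residues
        control_fp.write_json(fpdir / f"control_{t.id}.json")

        fingerprints[t.id] = {}
        for pose in read_poses(t.poses, energies, t.id):
            fp = fingerprint(
                pose, receptor, config.geometry, target_id=t.id, accelerated=True
            )
            fingerprints[t.id][pose.ligand_id] = fp
            fp.write_json(fpdir / f"{pose.ligand_id}_{t.id}.json")
        logger.info(
            "target %s: %d poses fingerprinted (control: %d residues)",
            t.id, len(fingerprints[t.id]), len(controls[t.id]),
        )

    ranked = score_annotated_library(
        properties, risk, metabolism, energies, fingerprints, controls,
        interpretation=config.similarity_interpretation,
        normalize=config.normalize,
    )
    for rec in ranked:
        if rec.flags:
            logger.warning("ligand %s flagged: %s", rec.ligand_id, ",".join(rec.flags))

    frame = scores_frame(ranked)
    scores_path = out / "scores.csv"
    frame.to_csv(scores_path, index=False, float_format="%.4f")
    ranked_path = out / "ranked.csv"
    frame.drop_duplicates("ligand_id")[
        ["ligand_id", "composite", "rank", "flags"]
    ].sort_values("rank").to_csv(ranked_path, index=False, float_format="%.4f")

    manifest = {
        "seed": config.seed,
        "similarity_interpretation": config.similarity_interpretation,
        "normalize": config.normalize,
        "geometry": config.geometry.to_dict(),
        "targets": [
            {
                "id": t.id,
                "receptor": str(t.receptor),
                "control_pose": str(t.control_pose),
                "poses": str(t.poses),
            }
            for t in config.targets
        ],
        "inputs": {
            "energies": str(config.energies),
            "properties": str(config.properties),
            "risk": str(config.risk),
            "metabolism": str(config.metabolism),
        },
        "versions": _library_versions(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {
        "scores": scores_path,
        "ranked": ranked_path,
        "manifest": manifest_path,
        "fingerprints": fpdir,
    }
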