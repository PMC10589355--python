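"""Virtual-screening score: binding-mode similarity, point rules, composite, ranking.

The composite per ligand is

    score = sum over targets of (|BE| + %similarityBM)
            + drug-likeness points + toxicity points + metabolism penalty

with the ligand-level point terms counted once.  Units are deliberately mixed
(kcal/mol magnitudes summed with percentages and points) -- the protocol is
additive as stated, with an optional normalization switch left off by default.

%similarityBM is interpreted as the fraction of the CONTROL ligand's
interacting residues that the test ligand shares: 100 x |test ∩ control| /
|control|.  A literal count-ratio reading (100 x |test| / |control|) is
available behind ``interpretation="count_ratio"`` for comparison only; it
rewards promiscuous binders and can exceed 100.

Drug-likeness ranges (all inclusive, 10 points each, as used by the protocol;
note the donor/acceptor ranges penalize LOW counts, a deliberate departure
from the classic rule-of-five which only caps them):

    molecular weight 200-500 g/mol; log P 2-5; HBA 5-10; HBD 2-5
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .chem import PropertySet
from .interactions import ContactFingerprint

__all__ = [
    "MetabolismAnnotation",
    "RiskAnnotation",
    "ScoreComponents",
    "VSRecord",
    "composite_score",
    "lipinski_points",
    "metabolism_penalty",
    "rank_library",
    "read_metabolism_csv",
    "read_risk_csv",
    "similarity_bm",
    "tox_points",
]

RISK_ENDPOINTS = ("mutagenicity", "teratogenicity", "tumorigenicity", "irritability")
RISK_LEVELS = ("high", "medium", "low")
_RISK_POINTS = {"high": 0, "medium": 10, "low": 20}
_METABOLISM_PENALTY = {"high": -20, "medium": -15, "low": -10}

LIPINSKI_RANGES = {
    "mw": (200.0, 500.0),
    "logp": (2.0, 5.0),
    "hba": (5, 10),
    "hbd": (2, 5),
}


@dataclass(frozen=True)
class RiskAnnotation:
    """Categorical toxicity-risk levels for the four screened endpoints."""

    ligand_id: str
    levels: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [e for e in RISK_ENDPOINTS if e not in self.levels]
        if missing:
            raise ValueError(f"{self.ligand_id}: missing endpoints {missing}")
        bad = {e: v for e, v in self.levels.items() if v not in RISK_LEVELS}
        if bad:
            raise ValueError(f"{self.ligand_id}: unknown risk levels {bad}")


@dataclass(frozen=True)
class MetabolismAnnotation:
    """Predisposition to toxic-metabolite formation.

    Annotations are expected to be restricted, upstream, to the variable
    moiety added by amide coupling (the decorated part of the scaffold).
    """

    ligand_id: str
    predisposition: str
    restricted_moiety: Optional[str] = None

    def __post_init__(self) -> None:
        if self.predisposition not in RISK_LEVELS:
            raise ValueError(
                f"{self.ligand_id}: unknown predisposition {self.predisposition!r}"
            )


@dataclass(frozen=True)
class ScoreComponents:
    """Per-target score pieces for one ligand."""

    abs_be: float            # |binding energy|, kcal/mol
    sim_bm: float            # %similarityBM in [0, 100]
    lipinski_points: int
    tox_points: int
    metabolism_penalty: int

    def __post_init__(self) -> None:
        if self.abs_be < 0:
            raise ValueError("abs_be is a magnitude and must be >= 0")


@dataclass
class VSRecord:
    ligand_id: str
    components: dict[str, ScoreComponents]  # target_id -> components
    composite: float = 0.0
    rank: Optional[int] = None
    flags: tuple[str, ...] = ()


ResidueSetLike = Union[ContactFingerprint, Iterable]


def _residue_set(obj: ResidueSetLike) -> frozenset:
    if isinstance(obj, ContactFingerprint):
        return obj.residues
    return frozenset(obj)


def similarity_bm(
    test: ResidueSetLike,
    control: ResidueSetLike,
    interpretation: str = "control_fraction",
) -> float:
    """Binding-mode similarity against a control ligand, in percent.

    ``control_fraction`` (default): 100 x |test ∩ control| / |control|.
    ``count_ratio``: the literal rule-of-three on set sizes (unbounded).
    An empty control residue set is an error (undefined statistic).
    """
    test_set = _residue_set(test)
    control_set = _residue_set(control)
    if not control_set:
        raise ValueError("control fingerprint has no interacting residues")
    if interpretation == "control_fraction":
        return 100.0 * len(test_set & control_set) / len(control_set)
    if interpretation == "count_ratio":
        return 100.0 * len(test_set) / len(control_set)
    raise ValueError(f"unknown interpretation {interpretation!r}")


def lipinski_points(props: PropertySet) -> int:
    """10 points per drug-likeness parameter inside its (inclusive) range."""
    values = {
        "mw": props.molecular_weight,
        "logp": props.log_p,
        "hba": props.hba,
        "hbd": props.hbd,
    }
    points = 0
    for key, (lo, hi) in LIPINSKI_RANGES.items():
        if lo <= values[key] <= hi:
            points += 10
    return points


def tox_points(risk: RiskAnnotation) -> int:
    """Sum of per-endpoint points: high 0, medium 10, low 20."""
    return sum(_RISK_POINTS[risk.levels[e]] for e in RISK_ENDPOINTS)


def metabolism_penalty(annot: MetabolismAnnotation) -> int:
    """high -> -20, medium -> -15, low -> -10."""
    return _METABOLISM_PENALTY[annot.predisposition]


def composite_score(components: Sequence[ScoreComponents]) -> float:
    """Summative final score over >= 1 targets; higher is better.

    Per-target |BE| and %similarityBM are summed over targets; the
    ligand-level terms (drug-likeness, toxicity, metabolism) are taken from
    the first entry and counted once.
    """
    if not components:
        raise ValueError("at least one target's components required")
    total = 0.0
    for comp in components:
        total += comp.abs_be + comp.sim_bm
    first = components[0]
    total += first.lipinski_points + first.tox_points + first.metabolism_penalty
    return total


def normalize_energy_terms(records: Sequence[VSRecord]) -> None:
    """Optional composite variant: rescale |BE| to a 0-100 range per target.

    Off by default throughout the pipeline; when requested, each target's
    |BE| values are min-max scaled across the library onto [0, 100] so the
    energy term is commensurate with the percentage/point terms, and
    composites are recomputed in place.  A degenerate (constant) energy
    column maps to 50.
    """
    targets = sorted({t for r in records for t in r.components})
    for target in targets:
        vals = [r.components[target].abs_be for r in records if target in r.components]
        lo, hi = min(vals), max(vals)
        for rec in records:
            if target not in rec.components:
                continue
            c = rec.components[target]
            scaled = 50.0 if hi == lo else 100.0 * (c.abs_be - lo) / (hi - lo)
            rec.components[target] = ScoreComponents(
                scaled, c.sim_bm, c.lipinski_points, c.tox_points,
                c.metabolism_penalty,
            )
    for rec in records:
        rec.composite = composite_score(
            [rec.components[t] for t in sorted(rec.components)]
        )


def rank_library(records: list[VSRecord]) -> list[VSRecord]:
    """Sort by composite descending, ties broken by ligand id ascending.

    Ranks 1..N are assigned in place; duplicate ligand ids are an error.
    The result is independent of input order.
    """
    ids = [r.ligand_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ligand ids: {dup}")
    ordered = sorted(records, key=lambda r: (-r.composite, r.ligand_id))
    for i, rec in enumerate(ordered, start=1):
        rec.rank = i
    return ordered


# -- annotation CSV I/O -------------------------------------------------------

def read_risk_csv(path) -> dict[str, RiskAnnotation]:
    """``ligand_id,mutagenicity,teratogenicity,tumorigenicity,irritability``"""
    df = pd.read_csv(path, dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        ann = RiskAnnotation(
            str(row.ligand_id),
            {e: getattr(row, e) for e in RISK_ENDPOINTS},
        )
        if ann.ligand_id in out:
            raise ValueError(f"duplicate risk annotation for {ann.ligand_id}")
        out[ann.ligand_id] = ann
    return out


def read_metabolism_csv(path) -> dict[str, MetabolismAnnotation]:
    """``ligand_id,predisposition``"""
    df = pd.read_csv(path, dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        ann = MetabolismAnnotation(str(row.ligand_id), row.predisposition)
        if ann.ligand_id in out:
            raise ValueError(f"duplicate metabolism annotation for {ann.ligand_id}")
        out[ann.ligand_id] = ann
    return out


def scores_frame(records: Sequence[VSRecord]) -> pd.DataFrame:
    """Long-format score table, one row per (ligand, target)."""
    rows = []
    for rec in records:
        for target_id in sorted(rec.components):
            c = rec.components[target_id]
            rows.append(
                {
                    "ligand_id": rec.ligand_id,
                    "target_id": target_id,
                    "abs_be": c.abs_be,
                    "sim_bm": c.sim_bm,
                    "lipinski_points": c.lipinski_points,
                    "tox_points": c.tox_points,
                    "metabolism_penalty": c.metabolism_penalty,
                    "composite": rec.composite,
                    "rank": rec.rank,
                    "flags": ";".join(rec.flags),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand_id", "target_id", "abs_be", "sim_bm", "lipinski_points",
            "tox_points", "metabolism_penalty", "composite", "rank", "flags",
        ],
    )
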