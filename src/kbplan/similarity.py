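"""Dice-based anatomical similarity matching and dose-constraint transfer.

The retrieval is a two-stage cascade: every database patient's PTV is first
rigidly aligned to the test patient's PTV, and the top ``k_ptv`` patients by
PTV Dice coefficient go on to an organ-at-risk stage where the rectum and
bladder are ranked independently (the single PTV translation is applied to
the candidate's OAR masks, preserving each patient's PTV-OAR geometry).  The
smallest achieved V50Gy among a structure's top ``k_oar`` matches becomes the
personalized optimization constraint for that structure; all other objective
rows come from the institutional protocol template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BinaryMask, StructureSet
from .registration import Translation, apply_translation, register_translation

#: Institutional protocol objective template: (structure, metric, value, units).
#: The rectum and bladder volume constraints are the rows replaced by the
#: personalized achievable values during constraint transfer.
PROTOCOL_OBJECTIVES: tuple[tuple[str, str, float, str], ...] = (
    ("PTV", "min_V50Gy", 96.0, "%"),
    ("PTV", "Dmax", 52.0, "Gy"),
    ("PTV", "Dmin", 49.5, "Gy"),
    ("PTV", "uniform_dose", 50.0, "Gy"),
    ("rectum", "V45Gy", 45.0, "%"),
    ("bladder", "V45Gy", 45.0, "%"),
    ("femoral_head_L", "V45Gy", 5.0, "%"),
    ("femoral_head_R", "V45Gy", 5.0, "%"),
    ("small_intestine", "V45Gy", 10.0, "%"),
    ("small_intestine", "Dmax", 50.0, "Gy"),
    ("spinal_cord", "Dmax", 42.0, "Gy"),
)

MATCHED_OARS = ("rectum", "bladder")


@dataclass
class PatientRecord:
    """One database entry: anatomy plus the achieved DVH parameters of its plan."""

    structures: StructureSet
    achieved_dvh: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        for (structure, metric), value in self.achieved_dvh.items():
            if metric.startswith("V") and not (0.0 <= value <= 100.0):
                raise ValueError(
                    f"{self.patient_id}: {structure} {metric}={value} outside [0, 100]%"
                )
            if metric.startswith("D") and value < 0:
                raise ValueError(f"{self.patient_id}: {structure} {metric} < 0 Gy")

    @property
    def patient_id(self) -> str:
        return self.structures.patient_id


@dataclass(frozen=True)
class SimilarityRecord:
    """Per-candidate result of PTV alignment + Dice scoring."""

    database_patient_id: str
    translation: Translation
    dsc: dict[str, float]

    def __post_init__(self) -> None:
        for name, value in self.dsc.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"DSC for {name} outside [0, 1]: {value}")


@dataclass
class MatchSelection:
    """Outcome of the two-stage match: ranked candidates and derived constraints."""

    ptv_top: list[SimilarityRecord]
    rectum_top: list[str]
    bladder_top: list[str]
    constraints: dict[str, float]

    def oar_top(self, oar: str) -> list[str]:
        return {"rectum": self.rectum_top, "bladder": self.bladder_top}[oar]

    def to_dict(self) -> dict:
        return {
            "ptv_top": [
                {
                    "patient_id": r.database_patient_id,
                    "translation": list(r.translation),
                    "dsc": dict(sorted(r.dsc.items())),
                }
                for r in self.ptv_top
            ],
            "rectum_top": list(self.rectum_top),
            "bladder_top": list(self.bladder_top),
            "constraints": dict(sorted(self.constraints.items())),
        }


@dataclass
class ObjectiveSet:
    """Optimization objective rows: protocol template with personalized OARs."""

    entries: list[tuple[str, str, float, str]]

    def value(self, structure: str, metric: str) -> float:
        for s, m, v, _ in self.entries:
            if s == structure and m == metric:
                return v
        raise KeyError((structure, metric))

    def to_dict(self) -> dict:
        return {
            "objectives": [
                {"structure": s, "metric": m, "value": v, "units": u}
                for s, m, v, u in self.entries
            ]
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of two masks."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("dice requires masks on one grid")
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        raise ValueError("dice of two empty masks is undefined (0/0)")
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def score_pair(test: PatientRecord, candidate: PatientRecord) -> SimilarityRecord:
    """Align candidate PTV to test PTV, then Dice PTV/rectum/bladder.

    The single PTV translation is applied to the candidate's rectum and
    bladder as well, so the OAR scores measure each organ's position
    relative to its own PTV.
    """
    needed = ("PTV",) + MATCHED_OARS
    for rec in (test, candidate):
        missing = [s for s in needed if s not in rec.structures]
        if missing:
            raise ValueError(f"{rec.patient_id}: missing structures {missing}")
    reg = register_translation(test.structures["PTV"], candidate.structures["PTV"])
    dsc = {
        name: dice(
            test.structures[name],
            apply_translation(candidate.structures[name], reg.translation),
        )
        for name in needed
    }
    return SimilarityRecord(candidate.patient_id, reg.translation, dsc)


def _ranked(records: list[SimilarityRecord], key: str) -> list[SimilarityRecord]:
    # descending DSC; ties broken by ascending patient ID for determinism
    return sorted(records, key=lambda r: (-r.dsc[key], r.database_patient_id))


def match_patient(
    test: PatientRecord,
    database: list[PatientRecord],
    k_ptv: int = 20,
    k_oar: int = 3,
) -> MatchSelection:
    """Two-stage similar-patient retrieval with constraint derivation.

    Every database patient (excluding any record with the test patient's ID,
    enforcing leave-one-out) is scored by :func:`score_pair`; the top
    ``k_ptv`` by PTV DSC advance, and among those the rectum and bladder are
    independently re-ranked to give ``k_oar`` matches per organ.  Derived
    constraints are the minimum achieved V50Gy over each organ's matches.
    """
    if not (k_ptv >= k_oar >= 1):
        raise ValueError("require k_ptv >= k_oar >= 1")
    pool = [p for p in database if p.patient_id != test.patient_id]
    if len(pool) < k_ptv:
        raise ValueError(
            f"database has {len(pool)} eligible patients but k_ptv={k_ptv}; "
            "lower k_ptv or enlarge the database"
        )
    scored = [score_pair(test, cand) for cand in pool]
    ptv_top = _ranked(scored, "PTV")[:k_ptv]
    oar_tops = {
        oar: [r.database_patient_id for r in _ranked(ptv_top, oar)[:k_oar]]
        for oar in MATCHED_OARS
    }
    by_id = {p.patient_id: p for p in pool}
    constraints = {}
    for oar in MATCHED_OARS:
        values = []
        for pid in oar_tops[oar]:
            key = (oar, "V50Gy")
            if key not in by_id[pid].achieved_dvh:
                raise ValueError(f"patient {pid} lacks achieved {oar} V50Gy")
            values.append(by_id[pid].achieved_dvh[key])
        constraints[oar] = float(min(values))
    return MatchSelection(ptv_top, oar_tops["rectum"], oar_tops["bladder"], constraints)


def derive_constraints(
    selection: MatchSelection, database: list[PatientRecord]
) -> ObjectiveSet:
    """Build the personalized objective set from a match selection.

    The rectum and bladder protocol volume-constraint rows are replaced by
    V50Gy rows holding the minimum achieved value over that organ's matched
    patients; every other protocol row is copied verbatim.
    """
    by_id = {p.patient_id: p for p in database}
    personalized: dict[str, float] = {}
    for oar in MATCHED_OARS:
        values = []
        for pid in selection.oar_top(oar):
            rec = by_id.get(pid)
            if rec is None or (oar, "V50Gy") not in rec.achieved_dvh:
                raise ValueError(f"patient {pid} lacks achieved {oar} V50Gy")
            values.append(rec.achieved_dvh[(oar, "V50Gy")])
        personalized[oar] = float(min(values))
    entries = []
    for structure, metric, value, units in PROTOCOL_OBJECTIVES:
        if structure in personalized and metric.startswith("V"):
            entries.append((structure, "V50Gy", personalized[structure], "%"))
        else:
            entries.append((structure, metric, value, units))
    return ObjectiveSet(entries)


def score_table(records: list[SimilarityRecord]) -> pd.DataFrame:
    """Tabulate similarity records (one row per database patient)."""
    rows = [
        {
            "patient_id": r.database_patient_id,
            "dsc_ptv": r.dsc["PTV"],
            "dsc_rectum": r.dsc["rectum"],
            "dsc_bladder": r.dsc["bladder"],
            "tu": r.translation.u,
            "tv": r.translation.v,
            "tw": r.translation.w,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=[
        "patient_id", "dsc_ptv", "dsc_rectum", "dsc_bladder", "tu", "tv", "tw"
    ])
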