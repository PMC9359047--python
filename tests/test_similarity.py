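"""Dice algebra, two-stage matching, and constraint derivation."""

from __future__ import annotations

import numpy as np
import pytest

from kbplan.core import BinaryMask, StructureSet, VoxelGrid
from kbplan.registration import Translation, apply_translation
from kbplan.similarity import (
    PROTOCOL_OBJECTIVES,
    MatchSelection,
    PatientRecord,
    SimilarityRecord,
    derive_constraints,
    dice,
    match_patient,
    score_pair,
    score_table,
)

from conftest import random_mask

GRID = VoxelGrid((24, 24, 24), (2.0, 2.0, 2.0))


def block_mask(grid, lo, hi):
    values = np.zeros(grid.shape, bool)
    values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return BinaryMask(grid, values)


def make_record(pid, ptv, rectum, bladder, achieved=None) -> PatientRecord:
    sset = StructureSet(pid, {"PTV": ptv, "rectum": rectum, "bladder": bladder})
    return PatientRecord(sset, achieved or {})


def simple_record(pid, shift=(0, 0, 0), achieved=None) -> PatientRecord:
    ptv = block_mask(GRID, (8, 8, 8), (14, 14, 14))
    rectum = block_mask(GRID, (9, 15, 8), (13, 18, 14))
    bladder = block_mask(GRID, (9, 3, 9), (13, 7, 14))
    moved = [apply_translation(m, shift) for m in (ptv, rectum, bladder)]
    return make_record(pid, *moved, achieved=achieved)


class TestDice:
    def test_identical_masks_score_one(self, rng):
        m = random_mask(GRID, 0.3, rng)
        assert dice(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = block_mask(GRID, (0, 0, 0), (4, 4, 4))
        b = block_mask(GRID, (10, 10, 10), (14, 14, 14))
        assert dice(a, b) == 0.0

    def test_constructed_counts_give_half(self):
        # |a| = 100, |b| = 60, |a∩b| = 40 -> 2*40/160 = 0.5
        a = block_mask(GRID, (0, 0, 0), (10, 10, 1))     # 100 voxels
        b_vals = np.zeros(GRID.shape, bool)
        b_vals[0:10, 0:4, 0] = True                       # 40 overlapping
        b_vals[0:10, 12:14, 0] = True                     # 20 disjoint
        b = BinaryMask(GRID, b_vals)
        assert a.voxel_count == 100 and b.voxel_count == 60
        assert int((a.values & b.values).sum()) == 40
        assert dice(a, b) == 0.5

    def test_symmetry_and_translation_invariance(self, rng):
        a = block_mask(GRID, (6, 6, 6), (12, 12, 12))
        b = block_mask(GRID, (8, 7, 6), (13, 14, 12))
        assert dice(a, b) == dice(b, a)
        t = (2, -1, 3)
        assert dice(apply_translation(a, t), apply_translation(b, t)) == dice(a, b)

    def test_both_empty_rejected(self):
        empty = BinaryMask(GRID, np.zeros(GRID.shape, bool))
        with pytest.raises(ValueError):
            dice(empty, empty)

    def test_range_is_unit_interval(self, rng):
        for _ in range(10):
            a = random_mask(GRID, 0.2, rng)
            b = random_mask(GRID, 0.2, rng)
            assert 0.0 <= dice(a, b) <= 1.0


class TestScorePair:
    def test_exact_copy_scores_one_everywhere(self):
        test = simple_record("T")
        cand = simple_record("C")
        rec = score_pair(test, cand)
        assert rec.translation == Translation(0, 0, 0)
        assert rec.dsc == {"PTV": 1.0, "rectum": 1.0, "bladder": 1.0}

    def test_rigid_shift_fully_undone(self):
        test = simple_record("T")
        cand = simple_record("C", shift=(3, 2, 1))
        rec = score_pair(test, cand)
        assert rec.translation == Translation(-3, -2, -1)
        assert rec.dsc == {"PTV": 1.0, "rectum": 1.0, "bladder": 1.0}

    def test_independent_bladder_displacement_scores_by_overlap(self):
        test = simple_record("T")
        ptv = block_mask(GRID, (8, 8, 8), (14, 14, 14))
        rectum = block_mask(GRID, (9, 15, 8), (13, 18, 14))
        bladder = apply_translation(block_mask(GRID, (9, 3, 9), (13, 7, 14)), (2, 0, 0))
        cand = make_record("C", ptv, rectum, bladder)
        rec = score_pair(test, cand)
        assert rec.dsc["PTV"] == 1.0 and rec.dsc["rectum"] == 1.0
        # 4x4x5 blocks overlapping in 2x4x5 after a 2-voxel displacement
        assert rec.dsc["bladder"] == pytest.approx(2 * 40 / (80 + 80))

    def test_missing_structure_rejected(self):
        ptv = block_mask(GRID, (8, 8, 8), (14, 14, 14))
        sset = StructureSet("X", {"PTV": ptv})
        with pytest.raises(ValueError, match="missing structures"):
            score_pair(PatientRecord(sset), PatientRecord(sset))


def jittered_db(n, achieved_fn=None):
    """Database of geometrically distinct (non-rigid-shift) variants."""
    db = []
    for i in range(n):
        ptv = block_mask(GRID, (8, 8, 8), (15 + (i % 3), 14, 14))
        rectum = block_mask(GRID, (9, 15, 8), (13, 19 + (i % 2), 14))
        bladder = block_mask(GRID, (9, 3, 9), (14 + (i % 4), 7, 14))
        achieved = achieved_fn(i) if achieved_fn else {
            ("rectum", "V50Gy"): 20.0 + i,
            ("bladder", "V50Gy"): 30.0 + i,
        }
        db.append(make_record(f"P{i:02d}", ptv, rectum, bladder, achieved=achieved))
    return db


class TestMatchPatient:
    def test_exact_copy_dominates_all_rankings(self):
        test = simple_record("T")
        db = jittered_db(5)
        db[2] = simple_record(
            "P02", achieved={("rectum", "V50Gy"): 25.0, ("bladder", "V50Gy"): 35.0}
        )
        # degrade other candidates' OARs so rankings are informative
        sel = match_patient(test, db, k_ptv=3, k_oar=1)
        assert sel.ptv_top[0].database_patient_id == "P02"
        assert sel.ptv_top[0].dsc == {"PTV": 1.0, "rectum": 1.0, "bladder": 1.0}
        assert sel.rectum_top == ["P02"] and sel.bladder_top == ["P02"]
        assert sel.constraints == {"rectum": 25.0, "bladder": 35.0}

    def test_rankings_match_brute_force_sort_of_score_table(self):
        rng = np.random.default_rng(99)
        test_structs = {
            "PTV": random_mask(GRID, 0.15, rng),
            "rectum": random_mask(GRID, 0.05, rng),
            "bladder": random_mask(GRID, 0.05, rng),
        }
        test = PatientRecord(StructureSet("T", test_structs))
        db = []
        for i in range(8):
            structs = {
                "PTV": random_mask(GRID, 0.15, rng),
                "rectum": random_mask(GRID, 0.05, rng),
                "bladder": random_mask(GRID, 0.05, rng),
            }
            db.append(
                PatientRecord(
                    StructureSet(f"P{i}", structs),
                    {("rectum", "V50Gy"): 10.0 + i, ("bladder", "V50Gy"): 20.0 + i},
                )
            )
        sel = match_patient(test, db, k_ptv=5, k_oar=3)
        # independent oracle: full score table sorted with the same tie rule
        records = [score_pair(test, c) for c in db]
        table = score_table(records)
        ptv_sorted = table.sort_values(
            ["dsc_ptv", "patient_id"], ascending=[False, True]
        )["patient_id"].tolist()
        assert [r.database_patient_id for r in sel.ptv_top] == ptv_sorted[:5]
        kept = table[table.patient_id.isin(ptv_sorted[:5])]
        for oar, col in (("rectum", "dsc_rectum"), ("bladder", "dsc_bladder")):
            expected = kept.sort_values(
                [col, "patient_id"], ascending=[False, True]
            )["patient_id"].tolist()[:3]
            assert sel.oar_top(oar) == expected
        assert set(sel.rectum_top) <= set(ptv_sorted[:5])
        assert set(sel.bladder_top) <= set(ptv_sorted[:5])

    def test_all_identical_candidates_selected_by_id_order(self):
        test = simple_record("T")
        db = [simple_record(f"P{i}", achieved={("rectum", "V50Gy"): 10.0,
                                               ("bladder", "V50Gy"): 10.0})
              for i in range(5)]
        sel = match_patient(test, db, k_ptv=4, k_oar=2)
        assert [r.database_patient_id for r in sel.ptv_top] == ["P0", "P1", "P2", "P3"]
        assert sel.rectum_top == ["P0", "P1"]
        assert sel.bladder_top == ["P0", "P1"]

    def test_leave_one_out_excludes_same_id(self):
        test = simple_record("P00")
        db = jittered_db(5)
        sel = match_patient(test, db, k_ptv=4, k_oar=1)
        assert "P00" not in [r.database_patient_id for r in sel.ptv_top]

    def test_small_database_rejected_with_hint(self):
        test = simple_record("T")
        with pytest.raises(ValueError, match="lower k_ptv"):
            match_patient(test, jittered_db(3), k_ptv=5, k_oar=1)

    def test_constraint_lowers_when_lower_value_added(self):
        test = simple_record("T")
        db = jittered_db(6)
        sel = match_patient(test, db, k_ptv=6, k_oar=3)
        base = sel.constraints["rectum"]
        matched = set(sel.rectum_top)
        lowered = [
            simple_record(
                p.patient_id,
                achieved={
                    ("rectum", "V50Gy"): p.achieved_dvh[("rectum", "V50Gy")] - 5.0
                    if p.patient_id in matched
                    else p.achieved_dvh[("rectum", "V50Gy")],
                    ("bladder", "V50Gy"): p.achieved_dvh[("bladder", "V50Gy")],
                },
            )
            for p in db
        ]
        # regenerate geometry identical to db (simple_record is deterministic)
        for old, new in zip(db, lowered):
            new.structures.structures.update(old.structures.structures)
        sel2 = match_patient(test, lowered, k_ptv=6, k_oar=3)
        assert sel2.constraints["rectum"] <= base


class TestDeriveConstraints:
    def _selection(self, ids):
        return MatchSelection(
            ptv_top=[SimilarityRecord(i, Translation(0, 0, 0), {"PTV": 1.0})
                     for i in ids],
            rectum_top=list(ids),
            bladder_top=list(ids),
            constraints={},
        )

    def _db(self, rectum_vals, bladder_vals):
        return [
            simple_record(f"P{i}", achieved={("rectum", "V50Gy"): rv,
                                             ("bladder", "V50Gy"): bv})
            for i, (rv, bv) in enumerate(zip(rectum_vals, bladder_vals))
        ]

    def test_minimum_of_three_is_transferred(self):
        db = self._db([30.0, 25.5, 41.2], [33.0, 44.0, 39.0])
        obj = derive_constraints(self._selection(["P0", "P1", "P2"]), db)
        assert obj.value("rectum", "V50Gy") == 25.5
        assert obj.value("bladder", "V50Gy") == 33.0

    def test_equal_values_pass_through(self):
        db = self._db([17.0, 17.0, 17.0], [17.0, 17.0, 17.0])
        obj = derive_constraints(self._selection(["P0", "P1", "P2"]), db)
        assert obj.value("rectum", "V50Gy") == 17.0

    def test_template_rows_intact_except_personalized(self):
        db = self._db([30.0, 25.5, 41.2], [33.0, 44.0, 39.0])
        obj = derive_constraints(self._selection(["P0", "P1", "P2"]), db)
        assert len(obj.entries) == len(PROTOCOL_OBJECTIVES)
        for got, template in zip(obj.entries, PROTOCOL_OBJECTIVES):
            s, m, v, u = template
            if s in ("rectum", "bladder") and m.startswith("V"):
                assert got == (s, "V50Gy", {"rectum": 25.5, "bladder": 33.0}[s], "%")
            else:
                assert got == template

    def test_missing_achieved_value_names_patient(self):
        db = self._db([30.0, 25.5, 41.2], [33.0, 44.0, 39.0])
        db[1].achieved_dvh.pop(("rectum", "V50Gy"))
        with pytest.raises(ValueError, match="P1"):
            derive_constraints(self._selection(["P0", "P1", "P2"]), db)


class TestSelfRetrievalProperty:
    def test_duplicate_of_test_ranks_first_with_unit_dsc(self):
        test = simple_record("T")
        db = jittered_db(6)
        db.append(simple_record("DUP", achieved={("rectum", "V50Gy"): 1.0,
                                                 ("bladder", "V50Gy"): 1.0}))
        sel = match_patient(test, db, k_ptv=5, k_oar=2)
        assert sel.ptv_top[0].database_patient_id == "DUP"
        assert sel.ptv_top[0].dsc == {"PTV": 1.0, "rectum": 1.0, "bladder": 1.0}
        assert sel.rectum_top[0] == "DUP" and sel.bladder_top[0] == "DUP"
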