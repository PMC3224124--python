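import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from estcurate.catalog import Direction, PlateSheet, build_plate_sheets
from estcurate.collapse import collapse, group_clones
from estcurate.plateqc import (
    RelationKind,
    build_correction_plan,
    classify_relation,
    compute_plan_delta,
    detect_diagonals,
    match_matrix,
    scan_cross_library,
    scan_library,
)
from estcurate.simulate import (
    LibraryPlan,
    TranscriptomeModel,
    simulate_library,
    simulate_transcriptome,
)

from .oracles import brute_force_diagonals


def sheet(slots, library_id="L", batch=1, plate=1, direction=Direction.FIVE_PRIME):
    slots = list(slots) + [None] * (96 - len(slots))
    return PlateSheet(library_id, batch, plate, direction, slots)


def distinct_genes(n=96, prefix="g"):
    return [f"{prefix}{i:03d}" for i in range(n)]


class TestMatchMatrix:
    def test_identical_distinct_sheets_give_diagonal(self):
        g = distinct_genes()
        M = match_matrix(g, g)
        assert np.array_equal(M.cells, np.eye(96, dtype=bool))

    def test_disjoint_sets_all_false(self):
        M = match_matrix(distinct_genes(prefix="a"), distinct_genes(prefix="b"))
        assert not M.cells.any()

    def test_shift_by_one_gives_offset_diagonal(self):
        g = distinct_genes()
        shifted = g[1:] + [None]
        M = match_matrix(shifted, g)
        for i in range(96):
            for j in range(96):
                expected = (j == i + 1) and i < 95
                assert M.cells[i, j] == expected

    def test_nulls_never_match(self):
        M = match_matrix([None, "a"], [None, "a"])
        assert M.cells.tolist() == [[False, False], [False, True]]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            match_matrix([], ["a"])


class TestDetectDiagonals:
    def test_identity_full_diagonal(self):
        M = np.eye(96, dtype=bool)
        segs = detect_diagonals(M, min_run=4, max_gap=2)
        assert len(segs) == 1
        assert (segs[0].offset, segs[0].length, segs[0].n_matched) == (0, 96, 96)

    def test_shared_null_no_segment(self):
        M = match_matrix([None] * 10, [None] * 10)
        assert detect_diagonals(M, min_run=1, max_gap=0) == []

    def test_piecewise_well_slip(self):
        """Wells 0-39 align at offset 0; wells 40-95 at offset +1."""
        g = distinct_genes()
        b = g[:40] + [None] + g[40:95]  # slot j=41+ holds gene 40+
        M = match_matrix(g, b)
        segs = detect_diagonals(M, min_run=4, max_gap=2)
        offsets = sorted(s.offset for s in segs)
        assert offsets == [0, 1]
        by_offset = {s.offset: s for s in segs}
        assert by_offset[0].start_i == 0 and by_offset[0].n_matched == 40
        assert by_offset[1].start_i == 40 and by_offset[1].n_matched == 55
        # equals brute-force enumeration
        expected = brute_force_diagonals(M.cells, 4, 2)
        got = {(s.start_i, s.start_j, s.length, s.n_matched) for s in segs}
        assert got == expected

    def test_gap_tolerance(self):
        diag = np.zeros((10, 10), dtype=bool)
        for i in [0, 1, 2, 5, 6]:  # gap of 2 inside
            diag[i, i] = True
        segs = detect_diagonals(diag, min_run=5, max_gap=2)
        assert len(segs) == 1
        assert segs[0].length == 7 and segs[0].n_matched == 5
        assert segs[0].gap_positions == (3, 4)
        assert detect_diagonals(diag, min_run=5, max_gap=1) == []

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_equals_brute_force_on_random_matrices(self, data):
        n_a = data.draw(st.integers(5, 28))
        n_b = data.draw(st.integers(5, 28))
        density = data.draw(st.floats(0.05, 0.5))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        M = rng.random((n_a, n_b)) < density
        min_run = data.draw(st.integers(2, 5))
        max_gap = data.draw(st.integers(0, 3))
        segs = detect_diagonals(M, min_run=min_run, max_gap=max_gap)
        got = {(s.start_i, s.start_j, s.length, s.n_matched) for s in segs}
        assert got == brute_force_diagonals(M, min_run, max_gap)


class TestClassifyRelation:
    def test_correct_pair(self):
        g = distinct_genes()
        a = sheet(g, direction=Direction.FIVE_PRIME)
        b = sheet(g, direction=Direction.THREE_PRIME)
        rel = classify_relation(a, b)
        assert rel.kind is RelationKind.CORRECT_PAIR
        assert rel.matched_fraction == 1.0

    def test_swap_candidate(self):
        # annotated 3f matching 4r at high fraction, offset 0
        g = distinct_genes()
        a = sheet(g, plate=3, direction=Direction.FIVE_PRIME)
        b = sheet(g, plate=4, direction=Direction.THREE_PRIME)
        rel = classify_relation(a, b)
        assert rel.kind is RelationKind.SWAP_CANDIDATE

    def test_same_direction_duplicate(self):
        g = distinct_genes()
        a = sheet(g, plate=1, direction=Direction.FIVE_PRIME)
        b = sheet(g, plate=2, direction=Direction.FIVE_PRIME)
        assert classify_relation(a, b).kind is RelationKind.DUPLICATE

    def test_cross_library_duplicate(self):
        g = distinct_genes()
        a = sheet(g, library_id="L1")
        b = sheet(g, library_id="L2")
        assert classify_relation(a, b).kind is RelationKind.CROSS_LIBRARY_DUPLICATE

    def test_well_slip_kind(self):
        g = distinct_genes()
        slipped = [None] + g[:95]  # 3' labels shifted by +1
        a = sheet(g, direction=Direction.FIVE_PRIME)
        b = sheet(slipped, direction=Direction.THREE_PRIME)
        rel = classify_relation(a, b)
        assert rel.kind is RelationKind.WELL_SLIP
        assert 1 in rel.offsets

    def test_partial_duplicate(self):
        g = distinct_genes()
        half = g[:48] + distinct_genes(48, prefix="other")
        a = sheet(g, plate=1)
        b = sheet(half, plate=2)
        rel = classify_relation(a, b)
        assert rel.kind is RelationKind.PARTIAL_DUPLICATE
        assert 0.3 <= rel.matched_fraction < 0.8

    def test_low_evidence_unmatched(self):
        a = sheet(["x"] * 4)
        b = sheet(["x"] * 4, plate=2)
        rel = classify_relation(a, b)
        assert rel.kind is RelationKind.UNMATCHED
        assert rel.low_evidence

    def test_random_sheets_near_collision_expectation(self, rng):
        """Random plates from a diverse transcriptome: UNMATCHED, with the
        matched fraction near the analytic collision probability."""
        model = TranscriptomeModel(n_genes=5000, seed=9)
        p = simulate_transcriptome(model)["base"]
        collision = float(np.sum(p**2))  # chance two draws agree
        fracs = []
        for _ in range(40):
            a = sheet([f"G{i:05d}" for i in rng.choice(5000, 96, p=p)], plate=1)
            b = sheet([f"G{i:05d}" for i in rng.choice(5000, 96, p=p)], plate=2,
                      direction=Direction.THREE_PRIME)
            rel = classify_relation(a, b)
            assert rel.kind is RelationKind.UNMATCHED
            fracs.append(rel.matched_fraction)
        observed = np.mean(fracs)
        se = (collision * (1 - collision) / (40 * 96)) ** 0.5
        # detected diagonals bias alignment upward slightly; allow generous CI
        assert observed < collision + 5 * se + 0.01

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 5000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in rng.integers(0, 60, size=96)]
        other = [f"g{i}" for i in rng.integers(0, 60, size=96)]
        a = sheet(genes, plate=1)
        b = sheet(other, plate=2, direction=Direction.THREE_PRIME)
        r1 = classify_relation(a, b)
        r2 = classify_relation(b, a)
        assert r1.kind == r2.kind
        assert r1.matched_fraction == pytest.approx(r2.matched_fraction)


def _make_library(seed, library_id="LIB", stem="ST", bidirectional=1.0, q=0.04):
    model = TranscriptomeModel(n_genes=5000, seed=seed)
    probs = simulate_transcriptome(model)["base"]
    plan = LibraryPlan(library_id, "g", stem, n_batches=1, plates_per_batch=4,
                       bidirectional_fraction=bidirectional, misannotation_prob=q)
    cat, truth = simulate_library(probs, plan, np.random.default_rng(seed + 1))
    return cat, truth


class TestScanLibrary:
    def test_clean_library_only_correct_pairs(self, clean_scenario):
        sheets = build_plate_sheets(clean_scenario.catalog, "LIBCLEAN")
        rels = scan_library(sheets)
        kinds = {r.kind for r in rels}
        assert RelationKind.CORRECT_PAIR in kinds
        n_pairs = sum(r.kind is RelationKind.CORRECT_PAIR for r in rels)
        assert n_pairs == 8  # 2 batches x 4 plates
        assert kinds <= {RelationKind.CORRECT_PAIR, RelationKind.UNMATCHED}

    def test_duplicate_injection_recall(self):
        from estcurate.simulate import ErrorSpec, PlateDuplicate, inject_errors

        for seed in range(10):
            cat, truth = _make_library(seed)
            cat, truth = inject_errors(
                cat, ErrorSpec([PlateDuplicate("LIB", 1, 2, 3)]), truth)
            rels = scan_library(build_plate_sheets(cat, "LIB"))
            dup_pairs = {
                frozenset((r.plate_a[:3], r.plate_b[:3]))
                for r in rels if r.kind is RelationKind.DUPLICATE
            }
            assert frozenset({("LIB", 1, 2), ("LIB", 1, 3)}) in dup_pairs

    def test_single_direction_library_negative_control(self):
        for seed in range(10):
            cat, _ = _make_library(seed, bidirectional=0.0)
            rels = scan_library(build_plate_sheets(cat, "LIB"))
            assert all(r.kind is RelationKind.UNMATCHED for r in rels)


class TestScanCrossLibrary:
    def test_injected_copy_flagged(self):
        from estcurate.simulate import CrossLibraryCopy, ErrorSpec, inject_errors
        from estcurate.catalog import ESTCatalog

        cat_a, truth = _make_library(0, "LEAF", "LF")
        cat_b, truth_b = _make_library(50, "BERRY", "BR")
        truth.merge(truth_b)
        merged = ESTCatalog(reads=cat_a.reads + cat_b.reads,
                            libraries={**cat_a.libraries, **cat_b.libraries})
        merged, truth = inject_errors(
            merged, ErrorSpec([CrossLibraryCopy("BERRY", 1, 1, "LEAF", 1, 4, "LF")]),
            truth)
        hits = scan_cross_library({
            "LEAF": build_plate_sheets(merged, "LEAF"),
            "BERRY": build_plate_sheets(merged, "BERRY"),
        })
        assert hits
        assert all(r.kind is RelationKind.CROSS_LIBRARY_DUPLICATE for r in hits)
        involved = {r.plate_a[:3] for r in hits} | {r.plate_b[:3] for r in hits}
        assert ("LEAF", 1, 4) in involved and ("BERRY", 1, 1) in involved

    def test_no_contamination_negative_control(self):
        from estcurate.catalog import ESTCatalog

        for seed in range(10):
            cat_a, _ = _make_library(seed, "LEAF", "LF")
            cat_b, _ = _make_library(seed + 100, "BERRY", "BR")
            merged = ESTCatalog(reads=cat_a.reads + cat_b.reads,
                                libraries={**cat_a.libraries, **cat_b.libraries})
            hits = scan_cross_library({
                "LEAF": build_plate_sheets(merged, "LEAF"),
                "BERRY": build_plate_sheets(merged, "BERRY"),
            })
            assert hits == []


class TestCorrectionPlan:
    def test_empty_relations_empty_plan(self):
        plan = build_correction_plan([])
        assert plan.actions == [] and plan.unresolved == []

    def test_single_duplicate_removes_one_plate(self):
        from estcurate.simulate import ErrorSpec, PlateDuplicate, inject_errors

        cat, truth = _make_library(3)
        cat, truth = inject_errors(
            cat, ErrorSpec([PlateDuplicate("LIB", 1, 1, 2)]), truth)
        rels = scan_library(build_plate_sheets(cat, "LIB"))
        plan = build_correction_plan(rels)
        delta = compute_plan_delta(plan, cat)
        assert delta["LIB"] == 192  # one bidirectional plate: 96 x 2 reads
        table = collapse(group_clones(cat, plan))
        assert table.totals["LIB"] == truth.unique_clones["LIB"]

    def test_quadruplicated_set_keeps_one_pair(self):
        """1f=1r=2f=2r: one physical plate retained, counts halved."""
        from estcurate.simulate import ErrorSpec, PlateDuplicate, inject_errors

        cat, truth = _make_library(4)
        cat, truth = inject_errors(
            cat, ErrorSpec([PlateDuplicate("LIB", 1, 1, 2)]), truth)
        rels = scan_library(build_plate_sheets(cat, "LIB"))
        plan = build_correction_plan(rels)
        merged_plates = {
            a.sheet[:3] for a in plan.actions if a.kind.value == "MERGE_DUPLICATE"
        }
        assert merged_plates == {("LIB", 1, 2)}

    def test_swap_repair_restores_pairing(self):
        """A pair swap leaves multiplicities intact on full plates but pairs
        the wrong reads; repair must push the pair-disagreement rate back
        down to the misannotation level."""
        from estcurate.collapse import disagreement_rate
        from estcurate.simulate import ErrorSpec, PairSwap, inject_errors

        cat, truth = _make_library(5)
        cat2, truth = inject_errors(cat, ErrorSpec([PairSwap("LIB", 1, 1, 2)]), truth)
        broken_rate = disagreement_rate(group_clones(cat2), 2)
        assert broken_rate > 0.3  # half the plates pair unrelated clones
        rels = scan_library(build_plate_sheets(cat2, "LIB"))
        plan = build_correction_plan(rels)
        groups = group_clones(cat2, plan)
        fixed_rate = disagreement_rate(groups, 2)
        assert fixed_rate < 0.2  # back to ~2q
        assert collapse(groups).totals["LIB"] == truth.unique_clones["LIB"]

    def test_slip_realign_restores_pairing(self):
        from estcurate.simulate import ErrorSpec, WellSlip, inject_errors

        cat, truth = _make_library(6)
        cat2, truth = inject_errors(
            cat, ErrorSpec([WellSlip("LIB", 1, 1, "A9", 1)]), truth)
        rels = scan_library(build_plate_sheets(cat2, "LIB"))
        plan = build_correction_plan(rels)
        fixed = collapse(group_clones(cat2, plan))
        # the slipped 3' read at H12 fell off the edge, so one clone of
        # plate 1 is single-read; unique count still matches truth
        assert fixed.totals["LIB"] == truth.unique_clones["LIB"]
        groups = group_clones(cat2, plan)
        plate1 = [g for g in groups if g.clone_key and g.clone_key[3] == 1]
        assert sum(g.multiplicity == 2 for g in plate1) == 95

    def test_plan_never_increases_totals(self, mixed_scenario):
        cat = mixed_scenario.catalog
        rels = []
        sheets_by_lib = {}
        for lib in sorted(cat.libraries):
            sheets_by_lib[lib] = build_plate_sheets(cat, lib)
            rels += scan_library(sheets_by_lib[lib])
        rels += scan_cross_library(sheets_by_lib)
        plan = build_correction_plan(rels)
        before = collapse(group_clones(cat))
        after = collapse(group_clones(cat, plan))
        for lib in before.totals:
            assert after.totals.get(lib, 0) <= before.totals[lib]

    def test_merge_only_plan_never_increases_gene_counts(self):
        """With pure duplication errors (no re-pairing), no gene's count may
        grow and untouched plates are preserved exactly."""
        from estcurate.simulate import ErrorSpec, PlateDuplicate, inject_errors

        cat, truth = _make_library(8)
        cat2, truth = inject_errors(
            cat, ErrorSpec([PlateDuplicate("LIB", 1, 1, 2)]), truth)
        rels = scan_library(build_plate_sheets(cat2, "LIB"))
        plan = build_correction_plan(rels)
        before = collapse(group_clones(cat2))
        after = collapse(group_clones(cat2, plan))
        for g, n in after.counts["LIB"].items():
            assert n <= before.counts["LIB"].get(g, 0)
        # plates 3 and 4 untouched: their clone groups identical pre/post
        def plate34(groups):
            return sorted(
                (g.clone_key, tuple(sorted(g.read_ids)))
                for g in groups if g.clone_key and g.clone_key[3] in (3, 4)
            )
        assert plate34(group_clones(cat2)) == plate34(group_clones(cat2, plan))

    def test_mixed_scenario_restores_truth(self, mixed_scenario):
        cat = mixed_scenario.catalog
        rels = []
        sheets_by_lib = {}
        for lib in sorted(cat.libraries):
            sheets_by_lib[lib] = build_plate_sheets(cat, lib)
            rels += scan_library(sheets_by_lib[lib])
        rels += scan_cross_library(sheets_by_lib)
        plan = build_correction_plan(rels)
        table = collapse(group_clones(cat, plan))
        assert table.totals == mixed_scenario.truth.unique_clones

    def test_contradictory_component_excluded(self):
        g1 = distinct_genes(prefix="a")
        g2 = distinct_genes(prefix="b")
        sa = sheet(g1, plate=1)
        sb = sheet(g2, plate=2)
        # plate 3 matches both, but 1 and 2 do not match each other
        rel_ab = classify_relation(sa, sb)
        assert rel_ab.kind is RelationKind.UNMATCHED
        # plate 3's sheets fully match both plate 1 and plate 2
        rel_ac = classify_relation(sa, sheet(g1, plate=3))
        rel_bc = classify_relation(sb, sheet(g2, plate=3))
        plan = build_correction_plan([rel_ab, rel_ac, rel_bc])
        assert plan.unresolved
        assert all(a.kind.value == "EXCLUDE_PLATE" for a in plan.actions)
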