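"""Dot-plot curation of plate-level naming and duplication errors.

Two plate sheets (ordered 96-slot gene-ID vectors) are compared by a
binary match matrix, exactly as a dot plot compares two sequences:
M[i, j] is set where the gene IDs agree and both are non-null.  Diagonal
runs of matches reveal true plate pairings and their well offsets;
classification of every sheet pair yields a relation report from which a
count-correction plan (merges, exclusions, re-pairings, well realignments)
is assembled.

Detected error classes: well slips (piecewise offsets between a 5'/3'
pair), full plate duplication/triplication, swapped plate pairings,
partial plate duplication, and plates copied across libraries.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .catalog import (
    Direction,
    ESTCatalog,
    ESTRead,
    PlateSheet,
    WELLS_PER_PLATE,
    well_from_index,
)

logger = logging.getLogger(__name__)

SheetKey = tuple[str, int, int, str]  # (library_id, batch, plate, direction value)


@dataclass
class QCThresholds:
    min_run: int = 4
    max_gap: int = 2
    t_full: float = 0.80
    t_partial: float = 0.30
    min_comparable: int = 10
    abundant_fraction: float = 0.10  # genes filling more wells than this cannot seed runs


@dataclass
class MatchMatrix:
    seq_a: tuple
    seq_b: tuple
    cells: np.ndarray  # bool, |seq_a| x |seq_b|


def match_matrix(seq_a: Sequence[Optional[str]], seq_b: Sequence[Optional[str]]) -> MatchMatrix:
    """Binary dot plot of two gene-ID vectors. Nulls never match, even each other."""
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise ValueError("both sequences must be nonempty")
    # encode gene ids as ints; null -> -1 on one side, -2 on the other so they
    # can never compare equal
    codes: dict[str, int] = {}

    def enc(seq, null_code):
        out = np.empty(len(seq), dtype=np.int64)
        for i, g in enumerate(seq):
            if g is None:
                out[i] = null_code
            else:
                out[i] = codes.setdefault(g, len(codes))
        return out

    a = enc(seq_a, -1)
    b = enc(seq_b, -2)
    return MatchMatrix(tuple(seq_a), tuple(seq_b), a[:, None] == b[None, :])


@dataclass(frozen=True)
class DiagonalSegment:
    start_i: int
    start_j: int
    length: int  # span from first to last matched cell, gaps included
    n_matched: int
    gap_positions: tuple[int, ...] = ()  # i-coordinates of tolerated gaps

    @property
    def offset(self) -> int:
        return self.start_j - self.start_i

    @property
    def end_i(self) -> int:
        return self.start_i + self.length - 1

    def covers(self, i: int) -> bool:
        return self.start_i <= i <= self.end_i


def detect_diagonals(
    M: MatchMatrix | np.ndarray,
    min_run: int = 4,
    max_gap: int = 2,
    seed_mask: Optional[np.ndarray] = None,
) -> list[DiagonalSegment]:
    """All maximal diagonal match runs with >= min_run matched cells.

    Up to ``max_gap`` consecutive mismatch/null cells are tolerated inside a
    run; runs begin and end on matched cells.  ``seed_mask`` (same shape as
    the matrix) marks cells allowed to start or end a run: matches outside
    it (e.g. of highly abundant genes) may only extend runs.  A pair of
    sheets whose true offset changes mid-plate yields one segment per
    offset, so piecewise "well slips" appear as multiple segments.
    """
    cells = M.cells if isinstance(M, MatchMatrix) else np.asarray(M, dtype=bool)
    if seed_mask is None:
        seed = cells
    else:
        seed = cells & np.asarray(seed_mask, dtype=bool)
    n_a, n_b = cells.shape
    segments: list[DiagonalSegment] = []
    for offset in range(-(n_a - 1), n_b):
        i_lo = max(0, -offset)
        i_hi = min(n_a, n_b - offset)  # exclusive
        diag = cells[np.arange(i_lo, i_hi), np.arange(i_lo, i_hi) + offset]
        seed_diag = seed[np.arange(i_lo, i_hi), np.arange(i_lo, i_hi) + offset]
        segments.extend(
            _runs_on_diagonal(diag, seed_diag, i_lo, offset, min_run, max_gap)
        )
    return segments


def _runs_on_diagonal(diag, seed_diag, i_lo, offset, min_run, max_gap):
    """Greedy left-to-right chaining of matches along one diagonal."""
    out = []
    match_pos = np.flatnonzero(diag)
    k = 0
    while k < len(match_pos):
        if not seed_diag[match_pos[k]]:
            k += 1
            continue
        start = match_pos[k]
        last = start
        last_seed = start
        matched = [start]
        k += 1
        while k < len(match_pos) and match_pos[k] - last - 1 <= max_gap:
            last = match_pos[k]
            matched.append(last)
            if seed_diag[last]:
                last_seed = last
            k += 1
        # trim trailing non-seed matches
        while matched and matched[-1] > last_seed:
            matched.pop()
        end = matched[-1]
        n_matched = len(matched)
        if n_matched >= min_run:
            covered = set(range(start, end + 1))
            gaps = tuple(sorted(covered - set(matched)))
            out.append(
                DiagonalSegment(
                    start_i=int(start + i_lo),
                    start_j=int(start + i_lo + offset),
                    length=int(end - start + 1),
                    n_matched=int(n_matched),
                    gap_positions=tuple(int(g + i_lo) for g in gaps),
                )
            )
        # resume after the chained stretch (trailing weak matches may re-chain)
        k = int(np.searchsorted(match_pos, end + 1))
        while k < len(match_pos) and match_pos[k] <= end:
            k += 1
    return out


class RelationKind(str, Enum):
    CORRECT_PAIR = "CORRECT_PAIR"
    WELL_SLIP = "WELL_SLIP"
    DUPLICATE = "DUPLICATE"
    PARTIAL_DUPLICATE = "PARTIAL_DUPLICATE"
    SWAP_CANDIDATE = "SWAP_CANDIDATE"
    CROSS_LIBRARY_DUPLICATE = "CROSS_LIBRARY_DUPLICATE"
    UNMATCHED = "UNMATCHED"


@dataclass
class PlateRelation:
    plate_a: SheetKey
    plate_b: SheetKey
    kind: RelationKind
    matched_fraction: float
    offsets: tuple[int, ...] = ()
    offset_map: dict[int, int] = field(default_factory=dict)  # index in a -> offset
    segments: tuple[DiagonalSegment, ...] = ()
    low_evidence: bool = False
    n_comparable: int = 0
    n_matched: int = 0

    def involves(self, key: SheetKey) -> bool:
        return key in (self.plate_a, self.plate_b)


def _abundance_seed_mask(seq_a, seq_b, abundant_fraction: float) -> np.ndarray:
    """Cells whose gene fills > abundant_fraction of either sheet cannot seed."""

    def abundant(seq):
        counts: dict[str, int] = {}
        for g in seq:
            if g is not None:
                counts[g] = counts.get(g, 0) + 1
        limit = abundant_fraction * len(seq)
        return {g for g, c in counts.items() if c > limit}

    bad = abundant(seq_a) | abundant(seq_b)
    ok_a = np.array([g is not None and g not in bad for g in seq_a])
    ok_b = np.array([g is not None and g not in bad for g in seq_b])
    return ok_a[:, None] & ok_b[None, :]


def _complementary(a: PlateSheet, b: PlateSheet) -> bool:
    return {a.direction, b.direction} == {Direction.FIVE_PRIME, Direction.THREE_PRIME}


def classify_relation(
    plate_a: PlateSheet,
    plate_b: PlateSheet,
    segments: Optional[list[DiagonalSegment]] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> PlateRelation:
    """Classify the relationship between two plate sheets.

    The matched fraction is computed over wells where both sheets are
    non-null after the best (possibly piecewise) offset alignment implied
    by the detected diagonal segments.  Classification is symmetric in the
    two arguments.
    """
    a, b = plate_a, plate_b
    swapped = False
    if b.key() < a.key():  # canonical orientation for symmetry
        a, b = b, a
        swapped = True
        if segments is not None:
            segments = [
                DiagonalSegment(s.start_j, s.start_i, s.length, s.n_matched)
                for s in segments
            ]
    if segments is None:
        M = match_matrix(a.slots, b.slots)
        seed = _abundance_seed_mask(a.slots, b.slots, thresholds.abundant_fraction)
        segments = detect_diagonals(M, thresholds.min_run, thresholds.max_gap, seed)

    offset_map, offsets = _piecewise_offsets(segments, len(a.slots))
    n_matched = 0
    n_comparable = 0
    for i, ga in enumerate(a.slots):
        if ga is None:
            continue
        j = i + offset_map.get(i, 0)
        if not (0 <= j < len(b.slots)) or b.slots[j] is None:
            continue
        n_comparable += 1
        if ga == b.slots[j]:
            n_matched += 1
    frac = n_matched / n_comparable if n_comparable else 0.0

    if n_comparable < thresholds.min_comparable:
        kind, low = RelationKind.UNMATCHED, True
    else:
        low = False
        same_plate = a.plate_key() == b.plate_key()
        same_library = a.library_id == b.library_id
        if frac >= thresholds.t_full:
            if not same_library:
                kind = RelationKind.CROSS_LIBRARY_DUPLICATE
            elif _complementary(a, b) and same_plate:
                if offsets == (0,):
                    kind = RelationKind.CORRECT_PAIR
                else:
                    kind = RelationKind.WELL_SLIP
            elif _complementary(a, b):
                kind = RelationKind.SWAP_CANDIDATE
            else:
                kind = RelationKind.DUPLICATE
        elif frac >= thresholds.t_partial:
            kind = RelationKind.PARTIAL_DUPLICATE
        else:
            kind = RelationKind.UNMATCHED

    rel = PlateRelation(
        plate_a=a.key(), plate_b=b.key(), kind=kind, matched_fraction=frac,
        offsets=offsets, offset_map=offset_map, segments=tuple(segments),
        low_evidence=low, n_comparable=n_comparable, n_matched=n_matched,
    )
    if swapped:
        # report in caller's order; kind and fraction are orientation-free
        rel = replace(
            rel, plate_a=rel.plate_b, plate_b=rel.plate_a,
            offsets=tuple(sorted({-o for o in rel.offsets})),
            offset_map={i + o: -o for i, o in rel.offset_map.items()},
            segments=tuple(
                DiagonalSegment(s.start_j, s.start_i, s.length, s.n_matched)
                for s in rel.segments
            ),
        )
    return rel


def _piecewise_offsets(
    segments: list[DiagonalSegment], n: int
) -> tuple[dict[int, int], tuple[int, ...]]:
    """Per-index offset assignments from segments (strongest segment wins),
    with uncovered indices falling back to the dominant offset."""
    if not segments:
        return {}, ()
    by_strength = sorted(segments, key=lambda s: (-s.n_matched, abs(s.offset)))
    dominant = by_strength[0].offset
    offset_map = dict.fromkeys(range(n), dominant)
    for s in reversed(by_strength):  # weakest first so strongest overwrite
        for i in range(s.start_i, s.end_i + 1):
            if 0 <= i < n:
                offset_map[i] = s.offset
    used = tuple(sorted(set(offset_map.values())))
    return offset_map, used


def _pair_relations(
    sheets: list[PlateSheet], thresholds: QCThresholds
) -> list[PlateRelation]:
    rels = []
    for a, b in itertools.combinations(sorted(sheets, key=lambda s: s.key()), 2):
        rels.append(classify_relation(a, b, thresholds=thresholds))
    return rels


def _resolve_swaps(relations: list[PlateRelation], thresholds: QCThresholds) -> None:
    """Demote SWAP_CANDIDATEs to DUPLICATE when both plates also match their
    own annotated partners (a duplicated plate set, not a mis-pairing)."""
    well_paired: set[tuple[str, int, int]] = set()
    for r in relations:
        if r.kind in (RelationKind.CORRECT_PAIR, RelationKind.WELL_SLIP):
            lib, batch, plate, _ = r.plate_a
            well_paired.add((lib, batch, plate))
    for r in relations:
        if r.kind is RelationKind.SWAP_CANDIDATE:
            pa = r.plate_a[:3]
            pb = r.plate_b[:3]
            if pa in well_paired and pb in well_paired:
                r.kind = RelationKind.DUPLICATE


def scan_library(
    sheets: list[PlateSheet], thresholds: QCThresholds = QCThresholds()
) -> list[PlateRelation]:
    """Classify every unordered pair of sheets within one library,
    cross-batch pairs included."""
    if len(sheets) < 2:
        raise ValueError("need at least two sheets to scan")
    libs = {s.library_id for s in sheets}
    if len(libs) != 1:
        raise ValueError(f"scan_library expects a single library, got {sorted(libs)}")
    relations = _pair_relations(sheets, thresholds)
    _resolve_swaps(relations, thresholds)
    return relations


def scan_cross_library(
    sheets_by_library: dict[str, list[PlateSheet]],
    thresholds: QCThresholds = QCThresholds(),
) -> list[PlateRelation]:
    """Compare every plate in every library against plates of all other
    libraries; only inter-library duplicate hits are reported."""
    if len(sheets_by_library) < 2:
        raise ValueError("need sheets from at least two libraries")
    hits = []
    libs = sorted(sheets_by_library)
    for la, lb in itertools.combinations(libs, 2):
        for a in sheets_by_library[la]:
            for b in sheets_by_library[lb]:
                rel = classify_relation(a, b, thresholds=thresholds)
                if rel.kind is RelationKind.CROSS_LIBRARY_DUPLICATE:
                    hits.append(rel)
    return hits


# ---------------------------------------------------------------------------
# Correction plan


class ActionKind(str, Enum):
    EXCLUDE_PLATE = "EXCLUDE_PLATE"
    MERGE_DUPLICATE = "MERGE_DUPLICATE"
    REPAIR_PAIRING = "REPAIR_PAIRING"
    REALIGN_WELLS = "REALIGN_WELLS"


@dataclass
class CorrectionAction:
    kind: ActionKind
    sheet: SheetKey  # the sheet acted upon (for REPAIR: the 3' sheet re-paired)
    provenance: list[PlateRelation] = field(default_factory=list)
    target_plate: Optional[tuple[str, int, int]] = None  # REPAIR: true partner plate
    offset_map: dict[int, int] = field(default_factory=dict)  # REALIGN: slot -> offset
    wells: Optional[list[int]] = None  # MERGE of a partial duplicate: slots dropped


@dataclass
class CorrectionPlan:
    actions: list[CorrectionAction] = field(default_factory=list)
    unresolved: list[SheetKey] = field(default_factory=list)
    read_count_delta: dict[str, int] = field(default_factory=dict)  # lib -> reads removed

    def apply(self, catalog: ESTCatalog) -> ESTCatalog:
        """Return a corrected copy of the catalog. Never adds reads."""
        drop_all = {
            a.sheet
            for a in self.actions
            if a.kind in (ActionKind.EXCLUDE_PLATE, ActionKind.MERGE_DUPLICATE)
            and a.wells is None
        }
        drop_wells: dict[SheetKey, set[int]] = {}
        repairs: dict[SheetKey, tuple[str, int, int]] = {}
        realigns: dict[SheetKey, dict[int, int]] = {}
        for a in self.actions:
            if a.kind is ActionKind.MERGE_DUPLICATE and a.wells is not None:
                drop_wells.setdefault(a.sheet, set()).update(a.wells)
            elif a.kind is ActionKind.REPAIR_PAIRING:
                repairs[a.sheet] = a.target_plate
            elif a.kind is ActionKind.REALIGN_WELLS:
                realigns[a.sheet] = a.offset_map
        out_reads: list[ESTRead] = []
        for r in catalog.reads:
            if r.clone is None:
                out_reads.append(r)
                continue
            c = r.clone
            key: SheetKey = (r.library_id, c.batch, c.plate, c.direction.value)
            if key in drop_all:
                continue
            idx = c.well_index
            if key in drop_wells and idx in drop_wells[key]:
                continue
            if key in realigns:
                off = realigns[key].get(idx, 0)
                true_idx = idx - off
                if not (0 <= true_idx < WELLS_PER_PLATE):
                    continue  # slipped off the plate edge; unrecoverable
                row, col = well_from_index(true_idx)
                c = replace(c, well_row=row, well_col=col)
            if key in repairs:
                _, batch, plate = repairs[key]
                c = replace(c, batch=batch, plate=plate)
            out_reads.append(replace(r, clone=c) if c is not r.clone else r)
        return ESTCatalog(reads=out_reads, libraries=dict(catalog.libraries))


def build_correction_plan(relations: list[PlateRelation]) -> CorrectionPlan:
    """Turn classified plate relations into count-correction actions.

    Duplicate components collapse to one retained physical plate (the
    lexicographically first annotation); swapped pairings become
    re-pairings so clone grouping joins the true partners; well slips
    become per-slot realignment maps; cross-library copies are excluded
    from the recipient library.  Contradictory duplicate evidence leaves
    the offending sheets excluded and flagged unresolved.
    """
    plan = CorrectionPlan()

    dup_rels = [
        r for r in relations
        if r.kind in (RelationKind.DUPLICATE, RelationKind.CROSS_LIBRARY_DUPLICATE,
                      RelationKind.PARTIAL_DUPLICATE)
    ]
    unmatched_pairs = {
        frozenset((r.plate_a[:3], r.plate_b[:3]))
        for r in relations
        if r.kind is RelationKind.UNMATCHED and not r.low_evidence
    }

    # connected components over physical plates, full-duplicate edges only
    full_edges = [
        r for r in dup_rels if r.kind is not RelationKind.PARTIAL_DUPLICATE
    ]
    parent: dict[tuple, tuple] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    plate_sheets: dict[tuple, set[SheetKey]] = defaultdict(set)
    plate_provenance: dict[tuple, list[PlateRelation]] = defaultdict(list)
    for r in full_edges:
        pa, pb = r.plate_a[:3], r.plate_b[:3]
        union(pa, pb)
        plate_sheets[pa].add(r.plate_a)
        plate_sheets[pb].add(r.plate_b)
        plate_provenance[pa].append(r)
        plate_provenance[pb].append(r)

    components: dict[tuple, list[tuple]] = defaultdict(list)
    for p in plate_sheets:
        components[find(p)].append(p)

    merged: set[SheetKey] = set()
    excluded: set[SheetKey] = set()
    for comp_plates in components.values():
        comp_plates = sorted(comp_plates)
        if len(comp_plates) < 2:
            continue
        # contradictory evidence: two plates in one duplicate component that
        # are themselves positively non-matching
        contradictions = [
            pair for pair in itertools.combinations(comp_plates, 2)
            if frozenset(pair) in unmatched_pairs
        ]
        if contradictions:
            for p in comp_plates:
                for sheet in sorted(plate_sheets[p]):
                    plan.unresolved.append(sheet)
                    excluded.add(sheet)
                    plan.actions.append(CorrectionAction(
                        ActionKind.EXCLUDE_PLATE, sheet,
                        provenance=plate_provenance[p],
                    ))
            logger.warning("contradictory duplicate component %s excluded", comp_plates)
            continue
        libs = {p[0] for p in comp_plates}
        survivors = comp_plates
        if len(libs) > 1:
            # cross-library copy: the recipient (stray copy) is the library
            # contributing fewer plates to the component; a symmetric tie is
            # undecidable from relations alone, so both sides are excluded
            # and flagged unresolved
            by_lib: dict[str, list[tuple]] = defaultdict(list)
            for p in comp_plates:
                by_lib[p[0]].append(p)
            sizes = {len(v) for v in by_lib.values()}
            if len(by_lib) == 2 and len(sizes) == 1:
                for p in comp_plates:
                    for sheet in sorted(plate_sheets[p]):
                        plan.unresolved.append(sheet)
                        excluded.add(sheet)
                        plan.actions.append(CorrectionAction(
                            ActionKind.EXCLUDE_PLATE, sheet,
                            provenance=plate_provenance[p],
                        ))
                logger.warning(
                    "undecidable cross-library duplicate %s excluded", comp_plates)
                continue
            keep_lib = min(by_lib, key=lambda l: (-len(by_lib[l]), l))
            for lib, plates in by_lib.items():
                if lib == keep_lib:
                    continue
                for p in plates:
                    for sheet in sorted(plate_sheets[p]):
                        excluded.add(sheet)
                        plan.actions.append(CorrectionAction(
                            ActionKind.EXCLUDE_PLATE, sheet,
                            provenance=plate_provenance[p],
                        ))
            survivors = by_lib[keep_lib]
        # within-library duplicates among the surviving plates: keep the
        # annotation-consistent (lexicographically first) plate
        survivors = sorted(survivors)
        for p in survivors[1:]:
            for sheet in sorted(plate_sheets[p]):
                merged.add(sheet)
                plan.actions.append(CorrectionAction(
                    ActionKind.MERGE_DUPLICATE, sheet,
                    provenance=plate_provenance[p],
                ))

    # partial duplications: drop only the duplicated wells of the later plate
    for r in dup_rels:
        if r.kind is not RelationKind.PARTIAL_DUPLICATE:
            continue
        keep_key, drop_key = sorted((r.plate_a, r.plate_b))
        if drop_key in merged or drop_key in excluded:
            continue
        # wells of the dropped sheet covered by the detected duplicate span
        wells: set[int] = set()
        for s in r.segments:
            if drop_key == r.plate_a:
                wells.update(range(s.start_i, s.start_i + s.length))
            else:
                wells.update(range(s.start_j, s.start_j + s.length))
        wells &= set(range(WELLS_PER_PLATE))
        if wells:
            plan.actions.append(CorrectionAction(
                ActionKind.MERGE_DUPLICATE, drop_key, provenance=[r],
                wells=sorted(wells),
            ))

    for r in relations:
        if r.kind is RelationKind.SWAP_CANDIDATE:
            # re-pair the 3' sheet with the 5' sheet's plate
            a, b = r.plate_a, r.plate_b
            three = a if a[3] == Direction.THREE_PRIME.value else b
            five = b if three is a else a
            if three in merged or three in excluded:
                continue
            plan.actions.append(CorrectionAction(
                ActionKind.REPAIR_PAIRING, three, provenance=[r],
                target_plate=five[:3],
            ))
        elif r.kind is RelationKind.WELL_SLIP:
            a, b = r.plate_a, r.plate_b
            three = a if a[3] == Direction.THREE_PRIME.value else b
            if three in merged or three in excluded:
                continue
            if three == r.plate_b:
                # offset_map maps a-index -> offset; the 3' sheet's slot j sits
                # at j = i + o, so record j -> o for realignment
                omap = {i + o: o for i, o in r.offset_map.items()
                        if o != 0 and 0 <= i + o < WELLS_PER_PLATE}
            else:
                omap = {i: -o for i, o in r.offset_map.items() if o != 0}
            if omap:
                plan.actions.append(CorrectionAction(
                    ActionKind.REALIGN_WELLS, three, provenance=[r],
                    offset_map=omap,
                ))

    # conflict-freedom: a sheet both merged and excluded keeps only exclusion
    if merged & excluded:
        plan.actions = [
            a for a in plan.actions
            if not (a.kind is ActionKind.MERGE_DUPLICATE and a.sheet in excluded)
        ]
    return plan


def compute_plan_delta(plan: CorrectionPlan, catalog: ESTCatalog) -> dict[str, int]:
    """Reads removed per library when the plan is applied to the catalog."""
    before: dict[str, int] = defaultdict(int)
    for r in catalog.reads:
        before[r.library_id] += 1
    after_cat = plan.apply(catalog)
    after: dict[str, int] = defaultdict(int)
    for r in after_cat.reads:
        after[r.library_id] += 1
    delta = {lib: before[lib] - after.get(lib, 0) for lib in before}
    plan.read_count_delta = delta
    return delta


def relation_rows(relations: list[PlateRelation]) -> list[tuple]:
    """Flatten relations for TSV output (well labels, not indices)."""
    rows = []
    for r in relations:
        rows.append((
            _fmt_sheet(r.plate_a), _fmt_sheet(r.plate_b), r.kind.value,
            f"{r.matched_fraction:.4f}",
            ",".join(str(o) for o in r.offsets),
        ))
    return rows


def _fmt_sheet(key: SheetKey) -> str:
    from .catalog import _ROMAN

    lib, batch, plate, d = key
    letter = {"5": "f", "3": "r", "?": ""}[d]
    return f"{lib}:b{batch:02d}p{_ROMAN[plate]}{letter}"
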