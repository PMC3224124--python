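"""Data model and parsing for clone-named EST reads and their plate geometry.

A clone name such as ``CA48LN09IF-A9, 5'end`` encodes the library stem
(``CA48LN``), a zero-padded batch number (``09``), the plate within the
batch (Roman ``I``--``IV``, or Arabic ``1``--``4`` in some dialects), the
96-well coordinate (``A9``) and the sequencing direction.  This module
parses and formats such names, maintains the row-major well order
(A1..A12, B1.., ..H12), and materializes per-(batch, plate, direction)
"plate sheets": the ordered 96-slot gene-ID vectors that plate QC compares.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

ROWS = "ABCDEFGH"
N_COLS = 12
WELLS_PER_PLATE = 96

_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV"}
_FROM_ROMAN = {v: k for k, v in _ROMAN.items()}


class Direction(str, Enum):
    FIVE_PRIME = "5"
    THREE_PRIME = "3"
    UNKNOWN = "?"

    @property
    def suffix(self) -> str:
        if self is Direction.FIVE_PRIME:
            return ", 5'end"
        if self is Direction.THREE_PRIME:
            return ", 3'end"
        return ""

    @property
    def plate_letter(self) -> str:
        if self is Direction.FIVE_PRIME:
            return "F"
        if self is Direction.THREE_PRIME:
            return "R"
        return ""


class CloneNameError(ValueError):
    """Malformed clone name; ``component`` names the offending part."""

    def __init__(self, message: str, component: str):
        super().__init__(message)
        self.component = component


def well_order_index(well_row: str, well_col: int) -> int:
    """Row-major index of a 96-well coordinate: A1 -> 0, B1 -> 12, H12 -> 95."""
    if well_row not in ROWS:
        raise ValueError(f"invalid well row {well_row!r}: expected A-H")
    if not (1 <= well_col <= N_COLS):
        raise ValueError(f"invalid well column {well_col}: expected 1-12")
    return ROWS.index(well_row) * N_COLS + (well_col - 1)


def well_from_index(index: int) -> tuple[str, int]:
    """Inverse of :func:`well_order_index`."""
    if not (0 <= index < WELLS_PER_PLATE):
        raise ValueError(f"well index {index} out of range 0-95")
    return ROWS[index // N_COLS], index % N_COLS + 1


@dataclass(frozen=True, order=True)
class CloneName:
    """Parsed clone annotation. Direction is not part of clone identity."""

    library_stem: str
    batch: int
    plate: int  # 1..4, formatted as Roman I..IV
    well_row: str
    well_col: int
    direction: Direction = Direction.UNKNOWN

    def __post_init__(self):
        if self.batch < 1:
            raise ValueError(f"batch must be positive, got {self.batch}")
        if self.plate not in _ROMAN:
            raise ValueError(f"plate must be 1-4, got {self.plate}")
        well_order_index(self.well_row, self.well_col)  # validates

    @property
    def well(self) -> str:
        return f"{self.well_row}{self.well_col}"

    @property
    def well_index(self) -> int:
        return well_order_index(self.well_row, self.well_col)

    def clone_key(self) -> tuple[str, int, int, str, int]:
        """Clone identity: stem/batch/plate/well, excluding direction."""
        return (self.library_stem, self.batch, self.plate, self.well_row, self.well_col)

    def canonical(self) -> str:
        return (
            f"{self.library_stem}{self.batch:02d}{_ROMAN[self.plate]}"
            f"{self.direction.plate_letter}-{self.well}{self.direction.suffix}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


_NAME_RE = re.compile(
    r"""^
    (?P<stem>.+?)                    # library stem, may itself contain digits
    (?P<batch>\d{1,2})               # zero-padded batch number
    (?P<plate>IV|III|II|I|[1-4])     # plate within batch
    (?P<platesuffix>[A-Za-z]?)       # optional F/R (or other) plate letter
    -
    (?P<row>[A-Za-z])(?P<col>\d{1,2})
    (?:,\s*(?P<dir>[35])'\s*end)?
    \.?
    $""",
    re.VERBOSE,
)


def parse_clone_name(raw: str) -> CloneName:
    """Parse a deposited clone name into its components.

    >>> parse_clone_name("CA48LN09IF-A9, 5'end").clone_key()
    ('CA48LN', 9, 1, 'A', 9)
    """
    if not raw or not raw.strip():
        raise CloneNameError("empty clone name", component="name")
    m = _NAME_RE.match(raw.strip())
    if m is None:
        # Distinguish the well error from a structurally broken name.
        well_m = re.search(r"-([A-Za-z])(\d{1,2})\b", raw)
        if well_m and (well_m.group(1).upper() not in ROWS or not 1 <= int(well_m.group(2)) <= 12):
            raise CloneNameError(
                f"well {well_m.group(1)}{well_m.group(2)} out of range in {raw!r}",
                component="well",
            )
        raise CloneNameError(f"cannot parse clone name {raw!r}", component="name")
    row = m.group("row").upper()
    col = int(m.group("col"))
    if row not in ROWS or not (1 <= col <= N_COLS):
        raise CloneNameError(f"well {row}{col} out of range in {raw!r}", component="well")
    plate_tok = m.group("plate")
    plate = _FROM_ROMAN.get(plate_tok, None)
    if plate is None:
        plate = int(plate_tok)
    direction = Direction.UNKNOWN
    if m.group("dir") == "5":
        direction = Direction.FIVE_PRIME
    elif m.group("dir") == "3":
        direction = Direction.THREE_PRIME
    return CloneName(
        library_stem=m.group("stem"),
        batch=int(m.group("batch")),
        plate=plate,
        well_row=row,
        well_col=col,
        direction=direction,
    )


@dataclass
class ESTRead:
    read_id: str
    library_id: str
    clone: Optional[CloneName]
    gene_id: Optional[str]
    confidence: float = 0.0

    def __post_init__(self):
        if self.confidence < 0:
            raise ValueError("confidence must be non-negative")
        if self.gene_id == "":
            self.gene_id = None


@dataclass
class LibraryInfo:
    library_id: str
    group_label: str
    orientation: str = "both"  # one of {"5'", "3'", "both", "n.d."}
    normalized: bool = False


@dataclass
class ESTCatalog:
    reads: list[ESTRead] = field(default_factory=list)
    libraries: dict[str, LibraryInfo] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return a list of human-readable consistency problems (empty if OK)."""
        problems: list[str] = []
        seen: set[str] = set()
        for r in self.reads:
            if r.read_id in seen:
                problems.append(f"duplicate read_id {r.read_id}")
            seen.add(r.read_id)
            if r.library_id not in self.libraries:
                problems.append(f"read {r.read_id}: unknown library {r.library_id}")
        return problems

    def reads_of(self, library_id: str) -> list[ESTRead]:
        return [r for r in self.reads if r.library_id == library_id]


@dataclass
class PlateSheet:
    """Ordered 96-slot gene-ID vector for one plate+direction."""

    library_id: str
    batch: int
    plate: int
    direction: Direction
    slots: list[Optional[str]]

    def __post_init__(self):
        if len(self.slots) != WELLS_PER_PLATE:
            raise ValueError("a plate sheet has exactly 96 slots")

    def key(self) -> tuple[str, int, int, str]:
        return (self.library_id, self.batch, self.plate, self.direction.value)

    def plate_key(self) -> tuple[str, int, int]:
        """Physical plate identity, ignoring direction."""
        return (self.library_id, self.batch, self.plate)

    @property
    def n_filled(self) -> int:
        return sum(s is not None for s in self.slots)


def build_plate_sheets(catalog: ESTCatalog, library_id: str) -> list[PlateSheet]:
    """One sheet per (batch, plate, direction) observed among the library's reads.

    Slot collisions (two reads claiming the same well+direction) are resolved
    by confidence, ties by lexicographically smaller read_id, and logged.
    """
    reads = [r for r in catalog.reads_of(library_id) if r.clone is not None]
    if not reads:
        raise ValueError(
            f"library {library_id} has no clone metadata; skip plate QC for it"
        )
    # winner per (batch, plate, direction, well)
    winners: dict[tuple, ESTRead] = {}
    for r in reads:
        c = r.clone
        slot = (c.batch, c.plate, c.direction, c.well_index)
        prev = winners.get(slot)
        if prev is None:
            winners[slot] = r
        else:
            keep, drop = prev, r
            if (r.confidence, _neg_id(r.read_id)) > (prev.confidence, _neg_id(prev.read_id)):
                keep, drop = r, prev
            winners[slot] = keep
            logger.warning(
                "slot collision in %s batch %d plate %s %s well %s: kept %s, dropped %s",
                library_id, c.batch, _ROMAN[c.plate], c.direction.name,
                c.well, keep.read_id, drop.read_id,
            )
    sheets: dict[tuple, PlateSheet] = {}
    for (batch, plate, direction, idx), r in winners.items():
        k = (batch, plate, direction)
        if k not in sheets:
            sheets[k] = PlateSheet(
                library_id=library_id, batch=batch, plate=plate,
                direction=direction, slots=[None] * WELLS_PER_PLATE,
            )
        sheets[k].slots[idx] = r.gene_id
    return [sheets[k] for k in sorted(sheets, key=lambda k: (k[0], k[1], k[2].value))]


class _neg_id(str):
    """Inverts string ordering so max() prefers the lexicographically smaller id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Catalog I/O

CATALOG_COLUMNS = ["read_id", "library_id", "clone_name", "direction", "gene_id", "confidence"]


def read_catalog(path, libraries: Optional[dict[str, LibraryInfo]] = None) -> ESTCatalog:
    """Read a TSV EST catalog.

    Columns: read_id, library_id, clone_name, direction, gene_id, confidence.
    Empty gene_id means unannotated; empty clone_name means no plate metadata.
    The direction column overrides (or supplies) the direction parsed from the
    clone name; values recognised: ``5``, ``3``, ``5'``, ``3'``, or empty.
    """
    reads: list[ESTRead] = []
    lib_ids: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in CATALOG_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"catalog {path} missing columns: {missing}")
        for row in reader:
            clone = None
            if row["clone_name"].strip():
                clone = parse_clone_name(row["clone_name"])
                d = row["direction"].strip().rstrip("'")
                if d == "5":
                    clone = replace(clone, direction=Direction.FIVE_PRIME)
                elif d == "3":
                    clone = replace(clone, direction=Direction.THREE_PRIME)
            reads.append(
                ESTRead(
                    read_id=row["read_id"],
                    library_id=row["library_id"],
                    clone=clone,
                    gene_id=row["gene_id"].strip() or None,
                    confidence=float(row["confidence"] or 0.0),
                )
            )
            lib_ids.add(row["library_id"])
    if libraries is None:
        libraries = {lid: LibraryInfo(lid, group_label=lid) for lid in sorted(lib_ids)}
    return ESTCatalog(reads=reads, libraries=libraries)


def write_catalog(catalog: ESTCatalog, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CATALOG_COLUMNS)
        for r in catalog.reads:
            clone_name = r.clone.canonical() if r.clone else ""
            direction = ""
            if r.clone and r.clone.direction is not Direction.UNKNOWN:
                direction = r.clone.direction.value
            w.writerow([r.read_id, r.library_id, clone_name, direction,
                        r.gene_id or "", repr(r.confidence)])


def read_library_metadata(path) -> dict[str, LibraryInfo]:
    """Library metadata from YAML (mapping or list) or TSV."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict):
            rows = [dict(library_id=k, **v) for k, v in data.items()]
        else:
            rows = data
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    out = {}
    for row in rows:
        out[str(row["library_id"])] = LibraryInfo(
            library_id=str(row["library_id"]),
            group_label=row["group_label"],
            orientation=row.get("orientation", "both"),
            normalized=_to_bool(row.get("normalized", False)),
        )
    return out


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in {"1", "true", "yes"}


def iter_fasta_clone_names(path) -> Iterable[tuple[str, CloneName]]:
    """Yield (record id, parsed clone name) from FASTA description lines.

    Sequence content is ignored; the clone name is expected as the first
    comma-delimited token pair of the description (``>id CLONE, 5'end``).
    """
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith(">"):
                continue
            header = line[1:].strip()
            parts = header.split(None, 1)
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else rec_id
            yield rec_id, parse_clone_name(desc)
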