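"""Synthetic EST catalogs with exact ground truth.

Generates clone-plate sequencing plans over a model transcriptome
(log-normal or Zipf abundances, optional per-group fold changes and
normalization flattening), emits reads with realistic clone names and
per-read misannotation, and injects the full taxonomy of plate-level
errors (well slips, plate duplication/triplication, pair swaps, partial
duplication, cross-library plate copies) after clean generation so that
every detector and estimator can be scored exactly against the truth
ledger.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .catalog import (
    CloneName,
    Direction,
    ESTCatalog,
    ESTRead,
    LibraryInfo,
    WELLS_PER_PLATE,
    well_from_index,
    well_order_index,
    write_catalog,
)

PlateRef = tuple[str, int, int]  # (library_id, batch, plate)


def gene_name(i: int) -> str:
    return f"G{i:05d}"


# ---------------------------------------------------------------------------
# Transcriptome model


@dataclass
class TranscriptomeModel:
    n_genes: int = 5000
    distribution: str = "lognormal"  # or "zipf"
    meanlog: float = 0.0
    sdlog: float = 1.5
    zipf_exponent: float = 1.2
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0


def simulate_transcriptome(
    model: TranscriptomeModel, groups: Sequence[str] = ("base",)
) -> dict[str, np.ndarray]:
    """Per-group gene sampling probabilities.

    Baseline abundances are drawn once from the model's seed; each group's
    designated DE genes are scaled by their fold change and the vector
    renormalized.
    """
    rng = np.random.default_rng(model.seed)
    if model.distribution == "lognormal":
        base = rng.lognormal(mean=model.meanlog, sigma=model.sdlog, size=model.n_genes)
    elif model.distribution == "zipf":
        ranks = rng.permutation(model.n_genes) + 1
        base = 1.0 / ranks.astype(float) ** model.zipf_exponent
    else:
        raise ValueError(f"unknown abundance distribution {model.distribution!r}")
    if np.any(base <= 0):
        raise ValueError("abundances must be positive")
    out: dict[str, np.ndarray] = {}
    for group in groups:
        p = base.copy()
        for gene, fc in model.fold_changes.get(group, {}).items():
            idx = int(gene[1:]) if isinstance(gene, str) else int(gene)
            p[idx] *= fc
        out[group] = p / p.sum()
    return out


# ---------------------------------------------------------------------------
# Library plan and clean generation


@dataclass
class LibraryPlan:
    library_id: str
    group_label: str
    stem: str
    n_batches: int = 4
    plates_per_batch: int = 4
    bidirectional_fraction: float = 0.8
    misannotation_prob: float = 0.08
    normalized: bool = False
    gamma: float = 1.0  # abundance-flattening exponent; 1.0 = unnormalized

    def __post_init__(self):
        if not (0.0 <= self.bidirectional_fraction <= 1.0):
            raise ValueError("bidirectional fraction must be in [0, 1]")
        if not (0.0 <= self.misannotation_prob <= 1.0):
            raise ValueError("misannotation probability must be in [0, 1]")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")

    @property
    def n_clones(self) -> int:
        return self.n_batches * self.plates_per_batch * WELLS_PER_PLATE


@dataclass
class TruthLedger:
    clone_gene: dict[str, str] = field(default_factory=dict)  # canonical clone -> true gene
    plate_pairings: list[tuple[PlateRef, PlateRef]] = field(default_factory=list)
    injected_errors: list[dict] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> fold change
    unique_clones: dict[str, int] = field(default_factory=dict)  # library -> true count

    def merge(self, other: "TruthLedger") -> None:
        self.clone_gene.update(other.clone_gene)
        self.plate_pairings.extend(other.plate_pairings)
        self.injected_errors.extend(other.injected_errors)
        self.de_genes.update(other.de_genes)
        self.unique_clones.update(other.unique_clones)


def _flatten(probabilities: np.ndarray, gamma: float) -> np.ndarray:
    if gamma == 1.0:
        return probabilities
    p = probabilities**gamma
    return p / p.sum()


def simulate_library(
    probabilities: np.ndarray,
    plan: LibraryPlan,
    seed: Union[int, np.random.Generator],
) -> tuple[ESTCatalog, TruthLedger]:
    """Draw a clone-per-well catalog for one library.

    Clones are sampled i.i.d. from the (optionally flattened) abundance
    vector, one clone per well, wells filled A1..H12.  Bidirectional plates
    emit one 5' and one 3' read per clone.  Each read's annotation is
    flipped to a uniformly random other gene with the plan's misannotation
    probability; correct annotations draw higher confidences so that
    confidence-based arbitration has signal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = _flatten(np.asarray(probabilities, dtype=float), plan.gamma)
    n_genes = len(p)
    truth = TruthLedger()
    reads: list[ESTRead] = []
    lib = plan.library_id
    for batch in range(1, plan.n_batches + 1):
        for plate in range(1, plan.plates_per_batch + 1):
            bidirectional = rng.random() < plan.bidirectional_fraction
            genes = rng.choice(n_genes, size=WELLS_PER_PLATE, p=p)
            directions = [Direction.FIVE_PRIME]
            if bidirectional:
                directions.append(Direction.THREE_PRIME)
                truth.plate_pairings.append(
                    ((lib, batch, plate), (lib, batch, plate))
                )
            for idx in range(WELLS_PER_PLATE):
                row, col = well_from_index(idx)
                true_gene = gene_name(int(genes[idx]))
                key_clone = CloneName(plan.stem, batch, plate, row, col)
                truth.clone_gene[key_clone.canonical()] = true_gene
                for d in directions:
                    clone = replace(key_clone, direction=d)
                    wrong = rng.random() < plan.misannotation_prob
                    if wrong:
                        g = int(rng.integers(0, n_genes - 1))
                        if g >= genes[idx]:
                            g += 1  # uniform over the other genes
                        obs_gene = gene_name(g)
                        conf = float(rng.uniform(0.0, 150.0))
                    else:
                        obs_gene = true_gene
                        conf = float(rng.uniform(100.0, 200.0))
                    reads.append(ESTRead(
                        read_id=f"{lib}.{clone.canonical()}",
                        library_id=lib,
                        clone=clone,
                        gene_id=obs_gene,
                        confidence=round(conf, 3),
                    ))
    truth.unique_clones[lib] = plan.n_clones
    catalog = ESTCatalog(
        reads=reads,
        libraries={lib: LibraryInfo(lib, plan.group_label, orientation="both",
                                    normalized=plan.normalized)},
    )
    return catalog, truth


def expected_pair_disagreement(q: float, n_genes: int) -> float:
    """Closed-form probability that the two reads of a clone disagree."""
    agree = (1 - q) ** 2 + q**2 / (n_genes - 1)
    return 1.0 - agree


# ---------------------------------------------------------------------------
# Error injection


@dataclass
class WellSlip:
    library_id: str
    batch: int
    plate: int
    start_well: str  # e.g. "A9"
    offset: int  # labels of the 3' plate shift by this from start_well onward


@dataclass
class PlateDuplicate:
    library_id: str
    batch: int
    src_plate: int
    dst_plate: int


@dataclass
class PlateTriplicate:
    library_id: str
    batch: int
    src_plate: int
    dst_plates: tuple[int, int]


@dataclass
class PairSwap:
    library_id: str
    batch: int
    plate_x: int
    plate_y: int  # the 5' plate labels of x and y are exchanged


@dataclass
class PartialDuplicate:
    library_id: str
    batch: int
    src_plate: int
    dst_plate: int
    fraction: float = 0.5


@dataclass
class CrossLibraryCopy:
    src_library: str
    src_batch: int
    src_plate: int
    dst_library: str
    dst_batch: int
    dst_plate: int
    dst_stem: str


Injection = Union[WellSlip, PlateDuplicate, PlateTriplicate, PairSwap,
                  PartialDuplicate, CrossLibraryCopy]


@dataclass
class ErrorSpec:
    injections: list[Injection] = field(default_factory=list)
    seed: int = 0


def _dst_plates(inj: Injection) -> list[PlateRef]:
    if isinstance(inj, WellSlip):
        return [(inj.library_id, inj.batch, inj.plate)]
    if isinstance(inj, PlateDuplicate):
        return [(inj.library_id, inj.batch, inj.dst_plate)]
    if isinstance(inj, PlateTriplicate):
        return [(inj.library_id, inj.batch, p) for p in inj.dst_plates]
    if isinstance(inj, PairSwap):
        return [(inj.library_id, inj.batch, inj.plate_x),
                (inj.library_id, inj.batch, inj.plate_y)]
    if isinstance(inj, PartialDuplicate):
        return [(inj.library_id, inj.batch, inj.dst_plate)]
    if isinstance(inj, CrossLibraryCopy):
        return [(inj.dst_library, inj.dst_batch, inj.dst_plate)]
    raise TypeError(f"unknown injection {inj!r}")


def inject_errors(
    catalog: ESTCatalog, spec: ErrorSpec, truth: Optional[TruthLedger] = None
) -> tuple[ESTCatalog, TruthLedger]:
    """Apply each injection literally to a clean catalog.

    Injections are applied after clean generation, so the returned ledger
    records exactly what was corrupted.  Two injections targeting the same
    destination plate raise an error.
    """
    truth = truth if truth is not None else TruthLedger()
    touched: set[PlateRef] = set()
    for inj in spec.injections:
        for ref in _dst_plates(inj):
            if ref in touched:
                raise ValueError(f"conflicting injections on plate {ref}")
            touched.add(ref)

    reads = list(catalog.reads)
    for inj in spec.injections:
        if isinstance(inj, WellSlip):
            reads = _apply_well_slip(reads, inj)
        elif isinstance(inj, PlateDuplicate):
            reads = _apply_duplicate(
                reads, (inj.library_id, inj.batch, inj.src_plate),
                [(inj.library_id, inj.batch, inj.dst_plate)], dst_stem=None)
            truth.unique_clones[inj.library_id] = (
                truth.unique_clones.get(inj.library_id, 0) - WELLS_PER_PLATE
            )
        elif isinstance(inj, PlateTriplicate):
            reads = _apply_duplicate(
                reads, (inj.library_id, inj.batch, inj.src_plate),
                [(inj.library_id, inj.batch, p) for p in inj.dst_plates],
                dst_stem=None)
            truth.unique_clones[inj.library_id] = (
                truth.unique_clones.get(inj.library_id, 0) - 2 * WELLS_PER_PLATE
            )
        elif isinstance(inj, PairSwap):
            reads = _apply_pair_swap(reads, inj)
        elif isinstance(inj, PartialDuplicate):
            n_wells = int(round(inj.fraction * WELLS_PER_PLATE))
            reads = _apply_duplicate(
                reads, (inj.library_id, inj.batch, inj.src_plate),
                [(inj.library_id, inj.batch, inj.dst_plate)],
                dst_stem=None, well_limit=n_wells)
            truth.unique_clones[inj.library_id] = (
                truth.unique_clones.get(inj.library_id, 0) - n_wells
            )
        elif isinstance(inj, CrossLibraryCopy):
            reads = _apply_duplicate(
                reads, (inj.src_library, inj.src_batch, inj.src_plate),
                [(inj.dst_library, inj.dst_batch, inj.dst_plate)],
                dst_stem=inj.dst_stem)
        truth.injected_errors.append(
            {"kind": type(inj).__name__, **asdict(inj)}
        )
    out = ESTCatalog(reads=reads, libraries=dict(catalog.libraries))
    return out, truth


def _read_plate(r: ESTRead) -> Optional[PlateRef]:
    if r.clone is None:
        return None
    return (r.library_id, r.clone.batch, r.clone.plate)


def _apply_well_slip(reads: list[ESTRead], inj: WellSlip) -> list[ESTRead]:
    target = (inj.library_id, inj.batch, inj.plate)
    start = well_order_index(inj.start_well[0], int(inj.start_well[1:]))
    out = []
    for r in reads:
        if (_read_plate(r) == target
                and r.clone.direction is Direction.THREE_PRIME
                and r.clone.well_index >= start):
            new_idx = r.clone.well_index + inj.offset
            if not (0 <= new_idx < WELLS_PER_PLATE):
                continue  # slipped off the plate edge
            row, col = well_from_index(new_idx)
            out.append(replace(r, clone=replace(r.clone, well_row=row, well_col=col)))
        else:
            out.append(r)
    return out


def _apply_duplicate(
    reads: list[ESTRead],
    src: PlateRef,
    dsts: list[PlateRef],
    dst_stem: Optional[str],
    well_limit: Optional[int] = None,
) -> list[ESTRead]:
    """Replace each destination plate's reads with a copy of the source
    plate's reads under the destination's annotation."""
    src_reads = [r for r in reads if _read_plate(r) == src]
    if not src_reads:
        raise ValueError(f"injection source plate {src} has no reads")
    drop: set[tuple] = set()
    for dst in dsts:
        for r in reads:
            if _read_plate(r) == dst:
                if well_limit is None or r.clone.well_index < well_limit:
                    drop.add((r.read_id,))
    out = [r for r in reads if (r.read_id,) not in drop]
    for dst_lib, dst_batch, dst_plate in dsts:
        for r in src_reads:
            if well_limit is not None and r.clone.well_index >= well_limit:
                continue
            stem = dst_stem if dst_stem is not None else r.clone.library_stem
            clone = replace(r.clone, library_stem=stem, batch=dst_batch, plate=dst_plate)
            out.append(replace(
                r,
                read_id=f"{dst_lib}.{clone.canonical()}.copy",
                library_id=dst_lib,
                clone=clone,
            ))
    return out


def _apply_pair_swap(reads: list[ESTRead], inj: PairSwap) -> list[ESTRead]:
    px = (inj.library_id, inj.batch, inj.plate_x)
    py = (inj.library_id, inj.batch, inj.plate_y)
    out = []
    for r in reads:
        plate = _read_plate(r)
        if r.clone is not None and r.clone.direction is Direction.FIVE_PRIME:
            if plate == px:
                out.append(replace(r, clone=replace(r.clone, plate=inj.plate_y)))
                continue
            if plate == py:
                out.append(replace(r, clone=replace(r.clone, plate=inj.plate_x)))
                continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Named end-to-end scenarios


@dataclass
class ScenarioResult:
    name: str
    seed: int
    catalog: Optional[ESTCatalog]
    truth: TruthLedger
    # count-level outputs for expression scenarios: group -> gene -> count
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)


SCENARIOS = ("clean", "table2_mixed", "root_vs_nonroot", "four_group_de")


def end_to_end_fixture(
    scenario: str, seed: int, out_dir: Optional[Union[str, Path]] = None
) -> ScenarioResult:
    """Generate a named scenario; optionally write catalog TSV + metadata
    YAML + truth JSON under ``out_dir``.  Scenarios are sized so the whole
    pipeline runs in well under a minute."""
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid scenarios: {', '.join(SCENARIOS)}"
        )
    builder = {
        "clean": _scenario_clean,
        "table2_mixed": _scenario_table2_mixed,
        "root_vs_nonroot": _scenario_root_vs_nonroot,
        "four_group_de": _scenario_four_group_de,
    }[scenario]
    result = builder(seed)
    if out_dir is not None:
        _write_fixture(result, Path(out_dir))
    return result


def _qc_plan(library_id: str, stem: str, group: str = "tissue") -> LibraryPlan:
    # misannotation 0.04 keeps cross-direction match fractions well above
    # the full-match threshold so injection recovery is separable
    return LibraryPlan(
        library_id=library_id, group_label=group, stem=stem,
        n_batches=2, plates_per_batch=4, bidirectional_fraction=1.0,
        misannotation_prob=0.04,
    )


def _scenario_clean(seed: int) -> ScenarioResult:
    model = TranscriptomeModel(n_genes=5000, seed=seed)
    probs = simulate_transcriptome(model)["base"]
    rng = np.random.default_rng(seed + 1)
    catalog, truth = simulate_library(probs, _qc_plan("LIBCLEAN", "CLN"), rng)
    return ScenarioResult("clean", seed, catalog, truth)


def _scenario_table2_mixed(seed: int) -> ScenarioResult:
    """Two libraries carrying one instance of every error class."""
    model = TranscriptomeModel(n_genes=5000, seed=seed)
    probs = simulate_transcriptome(model)["base"]
    rng = np.random.default_rng(seed + 1)
    cat_a, truth = simulate_library(probs, _qc_plan("LIBA", "LFA", "leaf"), rng)
    cat_b, truth_b = simulate_library(probs, _qc_plan("LIBB", "BRB", "berry"), rng)
    truth.merge(truth_b)
    catalog = ESTCatalog(
        reads=cat_a.reads + cat_b.reads,
        libraries={**cat_a.libraries, **cat_b.libraries},
    )
    spec = ErrorSpec(injections=[
        WellSlip("LIBA", 1, 1, start_well="A9", offset=1),
        PlateDuplicate("LIBA", 1, src_plate=2, dst_plate=3),
        PairSwap("LIBA", 2, plate_x=1, plate_y=2),
        PlateTriplicate("LIBB", 1, src_plate=1, dst_plates=(2, 3)),
        PartialDuplicate("LIBB", 2, src_plate=1, dst_plate=2, fraction=0.5),
        # mirrors the published cross-library case: the recipient plate is a
        # copy of a plate that is itself duplicated within its true library
        PlateDuplicate("LIBB", 2, src_plate=3, dst_plate=4),
        CrossLibraryCopy("LIBB", 2, 3, "LIBA", 2, 4, dst_stem="LFA"),
    ], seed=seed)
    catalog, truth = inject_errors(catalog, spec, truth)
    # cross-library copy replaces LIBA's plate (2,4): its 96 clones are not
    # independent observations of LIBA
    truth.unique_clones["LIBA"] -= WELLS_PER_PLATE
    return ScenarioResult("table2_mixed", seed, catalog, truth)


ROOT_TOTAL = 18_109
NONROOT_TOTAL = 291_233


def _scenario_root_vs_nonroot(
    seed: int,
    n_enriched: int = 50,
    fold: float = 8.0,
    n_genes: int = 5000,
) -> ScenarioResult:
    """Root vs non-root count tables at full survey scale with a known
    enriched-gene set.

    Enriched genes are sampled among genes of at least moderate baseline
    abundance (expected non-root count >= ~60) so the stated fold change is
    detectable at these totals.
    """
    rng = np.random.default_rng(seed)
    base_model = TranscriptomeModel(n_genes=n_genes, seed=seed)
    base = simulate_transcriptome(base_model)["base"]
    eligible = np.flatnonzero(base >= 2e-4)
    chosen = rng.choice(eligible, size=n_enriched, replace=False)
    fold_changes = {"root": {gene_name(int(i)): fold for i in chosen}}
    model = replace(base_model, fold_changes=fold_changes)
    probs = simulate_transcriptome(model, groups=("root", "nonroot"))
    root_counts = rng.multinomial(ROOT_TOTAL, probs["root"])
    nonroot_counts = rng.multinomial(NONROOT_TOTAL, probs["nonroot"])
    truth = TruthLedger(de_genes={gene_name(int(i)): fold for i in chosen})
    counts = {
        "root": {gene_name(i): int(c) for i, c in enumerate(root_counts) if c},
        "nonroot": {gene_name(i): int(c) for i, c in enumerate(nonroot_counts) if c},
    }
    return ScenarioResult(
        "root_vs_nonroot", seed, catalog=None, truth=truth, counts=counts,
        totals={"root": ROOT_TOTAL, "nonroot": NONROOT_TOTAL},
    )


FOUR_GROUPS = ("leaf", "stressed_leaf", "berry", "stressed_berry")


def _scenario_four_group_de(
    seed: int,
    n_genes: int = 1000,
    per_group_de: int = 25,
    fold: float = 6.0,
    depth: int = 12_000,
) -> ScenarioResult:
    """Four tissue/condition groups, each with its own enriched gene block."""
    rng = np.random.default_rng(seed)
    base_model = TranscriptomeModel(n_genes=n_genes, sdlog=1.0, seed=seed)
    base = simulate_transcriptome(base_model)["base"]
    eligible = list(np.flatnonzero(base >= np.quantile(base, 0.4)))
    fold_changes: dict[str, dict[str, float]] = {}
    truth = TruthLedger()
    chosen_all = rng.choice(eligible, size=per_group_de * len(FOUR_GROUPS), replace=False)
    for gi, group in enumerate(FOUR_GROUPS):
        block = chosen_all[gi * per_group_de:(gi + 1) * per_group_de]
        fold_changes[group] = {gene_name(int(i)): fold for i in block}
        for i in block:
            truth.de_genes[gene_name(int(i))] = fold
    model = replace(base_model, fold_changes=fold_changes)
    probs = simulate_transcriptome(model, groups=FOUR_GROUPS)
    counts = {}
    for group in FOUR_GROUPS:
        vec = rng.multinomial(depth, probs[group])
        counts[group] = {gene_name(i): int(c) for i, c in enumerate(vec) if c}
    return ScenarioResult(
        "four_group_de", seed, catalog=None, truth=truth, counts=counts,
        totals={g: depth for g in FOUR_GROUPS},
    )


# ---------------------------------------------------------------------------
# Fixture serialization (plain-text only)

TRUTH_SCHEMA_VERSION = 1


def _write_fixture(result: ScenarioResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.catalog is not None:
        write_catalog(result.catalog, out_dir / f"{result.name}.catalog.tsv")
        _write_metadata_yaml(result.catalog, out_dir / f"{result.name}.libraries.yaml")
    if result.counts:
        with open(out_dir / f"{result.name}.counts.tsv", "w", encoding="utf-8") as fh:
            fh.write("group\tgene_id\tcount\n")
            for group in sorted(result.counts):
                for gene in sorted(result.counts[group]):
                    fh.write(f"{group}\t{gene}\t{result.counts[group][gene]}\n")
    truth_doc = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "scenario": result.name,
        "seed": result.seed,
        "clone_gene": result.truth.clone_gene,
        "plate_pairings": [
            [list(a), list(b)] for a, b in result.truth.plate_pairings
        ],
        "injected_errors": result.truth.injected_errors,
        "de_genes": result.truth.de_genes,
        "unique_clones": result.truth.unique_clones,
        "totals": result.totals,
    }
    with open(out_dir / f"{result.name}.truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)


def _write_metadata_yaml(catalog: ESTCatalog, path: Path) -> None:
    import yaml

    doc = {
        lib.library_id: {
            "group_label": lib.group_label,
            "orientation": lib.orientation,
            "normalized": lib.normalized,
        }
        for lib in catalog.libraries.values()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Histogram-shaped catalogs (for redundancy arithmetic)


def catalog_from_histogram(
    total_reads: int,
    histogram: dict[int, int],
    library_id: str = "LIB",
    n_conflicting: dict[int, int] | None = None,
) -> ESTCatalog:
    """A catalog whose clone-multiplicity histogram is exactly as given.

    ``histogram`` maps multiplicity k >= 2 to the number of clone groups of
    that size; the remaining reads are singletons.  ``n_conflicting``
    optionally makes that many groups at each multiplicity carry one
    discordant gene assignment.
    """
    n_conflicting = n_conflicting or {}
    consumed = sum(k * n for k, n in histogram.items())
    if consumed > total_reads:
        raise ValueError("histogram consumes more reads than total_reads")
    reads: list[ESTRead] = []
    clone_serial = 0

    def next_clone() -> CloneName:
        nonlocal clone_serial
        # spread clones over synthetic batches; wells cycle A1..H12
        idx = clone_serial % WELLS_PER_PLATE
        plate = (clone_serial // WELLS_PER_PLATE) % 4 + 1
        batch = clone_serial // (WELLS_PER_PLATE * 4) + 1
        clone_serial += 1
        row, col = well_from_index(idx)
        return CloneName("SYN", batch, plate, row, col)

    serial = 0
    for k in sorted(histogram):
        for g in range(histogram[k]):
            clone = next_clone()
            conflict = g < n_conflicting.get(k, 0)
            gene = f"GENE{serial:06d}"
            for j in range(k):
                direction = Direction.FIVE_PRIME if j % 2 == 0 else Direction.THREE_PRIME
                member_gene = gene
                conf = 200.0
                if conflict and j == k - 1:
                    member_gene = f"GENE{serial:06d}x"
                    conf = 100.0
                reads.append(ESTRead(
                    read_id=f"{library_id}.r{serial:06d}.{j}",
                    library_id=library_id,
                    clone=replace(clone, direction=direction),
                    gene_id=member_gene,
                    confidence=conf,
                ))
            serial += 1
    n_singletons = total_reads - consumed
    for _ in range(n_singletons):
        clone = next_clone()
        reads.append(ESTRead(
            read_id=f"{library_id}.r{serial:06d}.0",
            library_id=library_id,
            clone=replace(clone, direction=Direction.FIVE_PRIME),
            gene_id=f"GENE{serial:06d}",
            confidence=200.0,
        ))
        serial += 1
    return ESTCatalog(
        reads=reads,
        libraries={library_id: LibraryInfo(library_id, group_label="synthetic")},
    )
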