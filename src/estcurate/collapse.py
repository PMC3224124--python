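"""Collapse re-sequenced clones into unique-clone counts.

A clone read bidirectionally (or re-read in the same direction) must be
counted exactly once when estimating expression from read frequencies.
Reads sharing a clone identity (library + stem/batch/plate/well, direction
excluded) form one group; each group contributes a single clone to the
gene whose assignment carries the greatest confidence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

from .catalog import ESTCatalog

if TYPE_CHECKING:  # pragma: no cover
    from .plateqc import CorrectionPlan


@dataclass
class CloneGroup:
    library_id: str
    clone_key: Optional[tuple]  # None for reads lacking clone metadata
    members: list[tuple[str, Optional[str], float]]  # (read_id, gene_id, confidence)

    @property
    def multiplicity(self) -> int:
        return len(self.members)

    @property
    def read_ids(self) -> list[str]:
        return [m[0] for m in self.members]

    @property
    def conflict(self) -> bool:
        genes = {g for _, g, _ in self.members if g is not None}
        return len(genes) >= 2

    @property
    def resolved_gene_id(self) -> Optional[str]:
        return resolve_gene(self)


def resolve_gene(group: CloneGroup) -> Optional[str]:
    """Gene of maximal confidence among annotated members; ties broken by
    lexicographically smaller gene_id. None iff all members unannotated."""
    annotated = [(conf, g) for _, g, conf in group.members if g is not None]
    if not annotated:
        return None
    best_conf = max(conf for conf, _ in annotated)
    return min(g for conf, g in annotated if conf == best_conf)


def group_clones(
    catalog: ESTCatalog, correction_plan: Optional["CorrectionPlan"] = None
) -> list[CloneGroup]:
    """Partition reads into clone groups.

    Reads without clone metadata each form a singleton group. If a
    correction plan is given, its exclusions / re-pairings / well
    realignments are applied to the catalog first.
    """
    if correction_plan is not None:
        catalog = correction_plan.apply(catalog)
    keyed: dict[tuple, CloneGroup] = {}
    loose: list[CloneGroup] = []
    for r in catalog.reads:
        member = (r.read_id, r.gene_id, r.confidence)
        if r.clone is None:
            loose.append(CloneGroup(r.library_id, None, [member]))
        else:
            key = (r.library_id,) + r.clone.clone_key()
            grp = keyed.get(key)
            if grp is None:
                keyed[key] = CloneGroup(r.library_id, key, [member])
            else:
                grp.members.append(member)
    return list(keyed.values()) + loose


@dataclass
class UniqueCloneTable:
    """Per-library unique-clone counts keyed by resolved gene."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)  # lib -> gene -> n
    unannotated: dict[str, int] = field(default_factory=dict)  # lib -> n unannotated clones
    totals: dict[str, int] = field(default_factory=dict)  # lib -> total unique clones
    multiplicity_histogram: dict[str, dict[int, int]] = field(default_factory=dict)
    conflicts: dict[str, int] = field(default_factory=dict)  # lib -> n conflicting groups

    @property
    def total_unique_clones(self) -> int:
        return sum(self.totals.values())

    def library_size(self, library_id: str) -> int:
        """Denominator for frequency estimation: all unique clones, annotated or not."""
        return self.totals[library_id]


def collapse(groups: list[CloneGroup]) -> UniqueCloneTable:
    """Each clone group contributes exactly one clone to its resolved gene.

    Conservation identity (checked by tests): total unique clones equals
    total reads minus sum over k of (k-1) * n_groups(k).
    """
    table = UniqueCloneTable()
    for g in groups:
        lib = g.library_id
        table.totals[lib] = table.totals.get(lib, 0) + 1
        hist = table.multiplicity_histogram.setdefault(lib, {})
        hist[g.multiplicity] = hist.get(g.multiplicity, 0) + 1
        if g.conflict:
            table.conflicts[lib] = table.conflicts.get(lib, 0) + 1
        gene = resolve_gene(g)
        if gene is None:
            table.unannotated[lib] = table.unannotated.get(lib, 0) + 1
        else:
            per_gene = table.counts.setdefault(lib, {})
            per_gene[gene] = per_gene.get(gene, 0) + 1
    return table


def disagreement_rate(groups: list[CloneGroup], k: int) -> float:
    """Fraction of multiplicity-k clone groups whose members disagree on gene id."""
    at_k = [g for g in groups if g.multiplicity == k]
    if not at_k:
        raise ValueError(f"no clone groups of multiplicity {k}")
    return sum(g.conflict for g in at_k) / len(at_k)


def multiplicity_histogram(groups: list[CloneGroup]) -> dict[int, int]:
    return dict(Counter(g.multiplicity for g in groups))


def unique_table_rows(table: UniqueCloneTable) -> list[tuple[str, str, int]]:
    """Flatten to sorted (library_id, gene_id, unique_count) rows for TSV output."""
    rows = []
    for lib in sorted(table.counts):
        for gene in sorted(table.counts[lib]):
            rows.append((lib, gene, table.counts[lib][gene]))
    return rows


def per_library_groups(groups: list[CloneGroup]) -> dict[str, list[CloneGroup]]:
    by_lib: dict[str, list[CloneGroup]] = defaultdict(list)
    for g in groups:
        by_lib[g.library_id].append(g)
    return dict(by_lib)
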