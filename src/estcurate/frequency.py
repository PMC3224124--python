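"""Per-library gene frequencies (transcripts per 10,000) and weighted-mean
combination of same-type libraries into group profiles.

The frequency of a gene in one library is its unique-clone count divided by
the library size (unique clones, annotated or not), scaled to 10,000.
Libraries of the same type are combined by a size-weighted mean, which is
algebraically identical to pooling the raw counts:

    sum_i n_i f_i / sum_i n_i == 10,000 * sum_i c_i / sum_i n_i
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .catalog import LibraryInfo
from .collapse import UniqueCloneTable

PER = 10_000.0


def gene_frequency(count: int, library_size: int) -> float:
    """Per-10,000 frequency of a gene observed ``count`` times in a library."""
    if library_size <= 0:
        raise ValueError(f"library size must be positive, got {library_size}")
    if not (0 <= count <= library_size):
        raise ValueError(f"count {count} outside [0, {library_size}]")
    return PER * count / library_size


def combine_weighted(frequencies: Sequence[float], sizes: Sequence[int]) -> float:
    """Size-weighted mean of per-library frequencies for one gene."""
    if len(frequencies) != len(sizes):
        raise ValueError("frequencies and sizes must align")
    total = sum(sizes)
    if total == 0:
        raise ValueError("total library size is zero")
    return sum(n * f for f, n in zip(frequencies, sizes)) / total


@dataclass
class FrequencyProfile:
    group_label: str
    library_sizes: dict[str, int]  # member library -> unique-clone size
    counts: dict[str, int] = field(default_factory=dict)  # gene -> pooled count
    contains_normalized: bool = False  # frequencies biased if True

    @property
    def total_size(self) -> int:
        return sum(self.library_sizes.values())

    def frequency(self, gene_id: str) -> float:
        return gene_frequency(self.counts.get(gene_id, 0), self.total_size)

    @property
    def genes(self) -> list[str]:
        return sorted(self.counts)


def build_group_profiles(
    unique_table: UniqueCloneTable,
    library_metadata: dict[str, LibraryInfo],
    groups: Sequence[str] | None = None,
) -> dict[str, FrequencyProfile]:
    """One pooled frequency profile per declared group.

    Genes absent from a member library count 0 there; pooling makes the
    combined frequency equal to the weighted mean of member frequencies.
    """
    by_group: dict[str, list[str]] = {}
    for lib_id, info in library_metadata.items():
        if lib_id in unique_table.totals:
            by_group.setdefault(info.group_label, []).append(lib_id)
    wanted = list(groups) if groups is not None else sorted(by_group)
    profiles: dict[str, FrequencyProfile] = {}
    for group in wanted:
        members = sorted(by_group.get(group, []))
        if not members:
            raise ValueError(f"group {group!r} has no member libraries with counts")
        prof = FrequencyProfile(
            group_label=group,
            library_sizes={lib: unique_table.totals[lib] for lib in members},
            contains_normalized=any(
                library_metadata[lib].normalized for lib in members
            ),
        )
        for lib in members:
            for gene, c in unique_table.counts.get(lib, {}).items():
                prof.counts[gene] = prof.counts.get(gene, 0) + c
        profiles[group] = prof
    return profiles


def frequency_matrix(
    profiles: dict[str, FrequencyProfile], genes: Sequence[str] | None = None
) -> tuple[list[str], list[str], list[list[float]]]:
    """(genes, groups, matrix) with one per-10k frequency column per group."""
    groups = sorted(profiles)
    if genes is None:
        genes = sorted({g for p in profiles.values() for g in p.counts})
    matrix = [[profiles[grp].frequency(g) for grp in groups] for g in genes]
    return list(genes), groups, matrix
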