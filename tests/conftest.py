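import numpy as np
import pytest

from estcurate.catalog import (
    CloneName,
    Direction,
    ESTCatalog,
    ESTRead,
    LibraryInfo,
    well_from_index,
)
from estcurate.simulate import end_to_end_fixture


def make_read(read_id, library_id="LIB1", stem="STEM", batch=1, plate=1,
              well="A1", direction=Direction.FIVE_PRIME, gene_id="G1",
              confidence=100.0):
    clone = CloneName(stem, batch, plate, well[0], int(well[1:]), direction)
    return ESTRead(read_id=read_id, library_id=library_id, clone=clone,
                   gene_id=gene_id, confidence=confidence)


def make_catalog(reads, libraries=None):
    if libraries is None:
        libraries = {
            lib: LibraryInfo(lib, group_label="tissue")
            for lib in {r.library_id for r in reads}
        }
    return ESTCatalog(reads=reads, libraries=libraries)


def full_plate_reads(library_id="LIB1", stem="STEM", batch=1, plate=1,
                     direction=Direction.FIVE_PRIME, genes=None):
    """96 reads covering A1..H12 of one plate+direction."""
    if genes is None:
        genes = [f"G{i:03d}" for i in range(96)]
    reads = []
    for idx in range(96):
        row, col = well_from_index(idx)
        reads.append(make_read(
            read_id=f"{library_id}.{batch}.{plate}.{direction.value}.{idx}",
            library_id=library_id, stem=stem, batch=batch, plate=plate,
            well=f"{row}{col}", direction=direction, gene_id=genes[idx],
        ))
    return reads


@pytest.fixture(scope="session")
def clean_scenario():
    return end_to_end_fixture("clean", seed=11)


@pytest.fixture(scope="session")
def mixed_scenario():
    return end_to_end_fixture("table2_mixed", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
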