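import pytest

from liwgs.alignment_io import InsertSizeProfile, ReadPairRecord
from liwgs.coverage_power import LibraryDesign


def make_pair(
    fragment_id="f1",
    sample="tumor",
    chrom_a="1",
    pos_a=1000,
    strand_a="+",
    chrom_b="1",
    pos_b=None,
    strand_b="-",
    mapq=60,
    insert_size=900,
    is_duplicate=False,
    is_mapped=True,
):
    """Concordant-by-default fragment record for hand-built fixtures."""
    if chrom_a != chrom_b:
        insert_size = 0
        if pos_b is None:
            pos_b = 1000
    elif pos_b is None:
        pos_b = pos_a + insert_size - 100
    return ReadPairRecord(
        fragment_id=fragment_id,
        sample=sample,
        chrom_a=chrom_a,
        pos_a=pos_a,
        strand_a=strand_a,
        chrom_b=chrom_b,
        pos_b=pos_b,
        strand_b=strand_b,
        mapq=mapq,
        insert_size=insert_size,
        is_duplicate=is_duplicate,
        is_mapped=is_mapped,
    )


@pytest.fixture
def si_design():
    """Short-insert library: 2 x 100 reads on 300-bp inserts."""
    return LibraryDesign(read_length=100, insert_size=300, genome_size=3.2e9)


@pytest.fixture
def li_design():
    """Long-insert library: 2 x 83 reads on 900-bp inserts."""
    return LibraryDesign(read_length=83, insert_size=900, genome_size=3.2e9)


@pytest.fixture
def flat_profile():
    """A normal-sample insert profile with range [700, 1100]."""
    return InsertSizeProfile(
        n_pairs=10_000, median=900.0, mean=900.0, sd=64.0, range_low=700.0, range_high=1100.0
    )
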