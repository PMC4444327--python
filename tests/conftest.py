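import numpy as np
import pytest

from cnvscan import AlignedRead, ChromMap


@pytest.fixture
def chrom_map():
    return ChromMap({"chr1": 10_000, "chr2": 5_000})


def make_read(
    chrom="chr1",
    start=0,
    read_length=60,
    mapq=60,
    insert_size=None,
    sample_id="A",
    proper=True,
):
    return AlignedRead(
        chrom=chrom,
        start=start,
        read_length=read_length,
        mapq=mapq,
        paired=insert_size is not None,
        insert_size=insert_size,
        proper_orientation=proper,
        sample_id=sample_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
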