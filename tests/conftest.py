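import numpy as np
import pytest

from sinefactory.tags import TagLibrary


def make_library(name, chrom_sizes, tags_by_chrom):
    """Build a TagLibrary from {chrom: [(pos, strand_char), ...]}."""
    arrays = {}
    for chrom, tags in tags_by_chrom.items():
        pos = np.array([p for p, _ in tags], dtype=np.int64)
        strand = np.array([1 if s == "+" else -1 for _, s in tags], dtype=np.int8)
        arrays[chrom] = (pos, strand)
    return TagLibrary.from_arrays(name, chrom_sizes, arrays)


@pytest.fixture
def small_sizes():
    return {"chr1": 10_000, "chr2": 4_000}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
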