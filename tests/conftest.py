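import numpy as np
import pytest

from oriscan.genome import GenomeIndex
from oriscan.mutcontext import MutationRecord


@pytest.fixture
def small_index():
    return GenomeIndex({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(chrom="chr1", pos=100, obs="TCT>TAT", sample="S1"):
    """MutationRecord from an observed class string."""
    ctx, mut = obs.split(">")
    return MutationRecord(chrom, pos, ctx[1], mut[1], sample, ctx)


@pytest.fixture
def make_rec():
    return make_record
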