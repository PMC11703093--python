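import numpy as np
import pandas as pd
import pytest

from recfin import synthetic as syn
from recfin.maps import RhoMap


def make_map(rows):
    """RhoMap from (chrom, start, end, rho) tuples."""
    return RhoMap(pd.DataFrame(rows, columns=["chrom", "start", "end", "rho"])).validate()


def uniform_map(length=100_000, step=200, rho=0.01, chrom="chr1"):
    starts = np.arange(0, length, step)
    return make_map(list(zip([chrom] * len(starts), starts, starts + step,
                             [rho] * len(starts))))


@pytest.fixture
def small_spec():
    return syn.SyntheticGenomeSpec({"chr1": 2_000_000, "chr2": 1_500_000}, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
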