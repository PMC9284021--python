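import numpy as np
import pandas as pd
import pytest

from ystrpop.data_io import HaplotypeTable


def make_table(values, populations, loci=None, sample_ids=None):
    """Build a HaplotypeTable from a nested list / array of repeat counts."""
    arr = np.asarray(values, dtype=float)
    n, L = arr.shape
    loci = loci or [f"L{i + 1}" for i in range(L)]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    alleles = pd.DataFrame(arr, index=pd.Index(sample_ids, name="SampleID"), columns=loci)
    return HaplotypeTable(alleles, pd.Series(list(populations), index=alleles.index, name="Population"))


@pytest.fixture
def toy_table():
    """Six samples, two populations, three loci, one missing call."""
    return make_table(
        [
            [14, 30, 11],
            [14, 31, 11],
            [15, 30, 12],
            [16, 29, 11],
            [16, 29, np.nan],
            [17, 28, 13.2],
        ],
        ["A", "A", "A", "B", "B", "B"],
        loci=["DYS19", "DYS389II", "DYS392"],
    )


def random_table(rng, n_samples, n_loci, n_pops=2, missing_rate=0.0):
    vals = rng.integers(8, 20, size=(n_samples, n_loci)).astype(float)
    if missing_rate:
        mask = rng.random(vals.shape) < missing_rate
        vals[mask] = np.nan
    pops = [f"P{1 + i % n_pops}" for i in range(n_samples)]
    return make_table(vals, pops)
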