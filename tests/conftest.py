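import numpy as np
import pandas as pd
import pytest

from methval.methio import BetaMatrix, IntensityTable, WGBSSiteTable
from methval.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20180918)


@pytest.fixture
def small_config():
    """Down-sized config for fast structural tests (defaults otherwise)."""
    return SimConfig(n_loci=400, n_reference_samples=40, seed=7)


@pytest.fixture
def default_config():
    return SimConfig(seed=11)


@pytest.fixture
def beta_matrix():
    return BetaMatrix(
        locus_ids=["cgA", "cgB", "cgC"],
        sample_ids=["s1", "s2"],
        values=np.array([[0.1, 0.2], [0.5, np.nan], [0.9, 1.0]]),
    )


@pytest.fixture
def intensity_table():
    return IntensityTable(
        pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "c1", "c2"],
                "M": [1000.0, 50.0, 190.0, 210.0],
                "U": [100.0, 900.0, 205.0, 195.0],
                "is_background_control": [False, False, True, True],
            }
        )
    )


@pytest.fixture
def wgbs_table():
    return WGBSSiteTable(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "pos": [100, 150, 42],
                "strand": ["+", "-", "+"],
                "context": ["CpG", "CpG", "CpG"],
                "level": [0.75, 0.0, 1.0],
                "coverage": [40, 12, 77],
            }
        )
    )


def quantile_oracle(values, p):
    """Independent linearly interpolated quantile at position (n-1)*p."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * p
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])
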