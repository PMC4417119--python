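import numpy as np
import pandas as pd
import pytest

from scnv.binning import MappabilityTrack, VariableBinning, compute_variable_bins


@pytest.fixture
def uniform_track():
    """One chromosome, 100 contiguous mappable bp."""
    return MappabilityTrack({"chr1": np.array([[0, 100]])}, {"chr1": 100})


@pytest.fixture
def uniform_bins(uniform_track):
    return compute_variable_bins(uniform_track, 10)


def make_bins(counts_per_chrom, bin_span=10, gc=None):
    """Simple uniform binning helper: {chrom: n_bins} with equal spans."""
    rows = []
    for chrom, n in counts_per_chrom.items():
        for i in range(n):
            rows.append({"chrom": chrom, "start": i * bin_span,
                         "end": (i + 1) * bin_span, "mappable_count": bin_span,
                         "gc": np.nan, "bad": False})
    df = pd.DataFrame(rows)
    if gc is not None:
        df["gc"] = gc
    return VariableBinning(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
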