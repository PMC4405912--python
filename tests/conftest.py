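import warnings

import numpy as np
import pandas as pd
import pytest

from microtime import OtuTimeSeries

# statsmodels emits convergence chatter on deliberately misspecified grids
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def toy_counts():
    """3-day x 2-OTU count table."""
    return pd.DataFrame(
        [[5, 5], [10, 0], [0, 10]],
        index=pd.Index([0, 1, 2], name="day"),
        columns=["OTU_A", "OTU_B"],
    )


@pytest.fixture
def toy_series(toy_counts):
    return OtuTimeSeries(counts=toy_counts)


@pytest.fixture
def bloom_series():
    """Five OTUs, four days identical, fifth day OTU E down 90% at double
    sequencing depth.  Counts are exact multiples of the true fractions, so
    normalization arithmetic is exact."""
    counts = pd.DataFrame(
        [[8200] * 5] * 4 + [[20000, 20000, 20000, 20000, 2000]],
        index=pd.Index(range(5), name="day"),
        columns=list("ABCDE"),
    )
    return OtuTimeSeries(counts=counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
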