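import numpy as np
import pytest

from axiszone import ZoneCountTable

ZONES6 = [str(i) for i in range(1, 7)]


@pytest.fixture
def filter_toy_table():
    """4 transcripts x 6 zones with library sizes forced to 1e6.

    CPM then equals the count: all-zero; 0.4 everywhere; 0.6 in one zone
    only (counts scaled by 10 on a 1e7 library to keep them integral);
    10 everywhere.
    """
    counts = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [4, 4, 4, 4, 4, 4],
            [6, 0, 0, 0, 0, 0],
            [100, 100, 100, 100, 100, 100],
        ]
    )
    return ZoneCountTable(
        ["zero", "dim", "spike", "bright"],
        ZONES6,
        counts,
        library_sizes=[10_000_000] * 6,
    )


@pytest.fixture
def random_table():
    """Factory for small random count tables with a fixed generator."""

    def make(n_transcripts=10, n_zones=3, seed=0, low=1, high=800):
        rng = np.random.default_rng(seed)
        counts = rng.integers(low, high, size=(n_transcripts, n_zones))
        return ZoneCountTable(
            [f"t{i}" for i in range(n_transcripts)],
            [str(z + 1) for z in range(n_zones)],
            counts.astype(np.int64),
        )

    return make
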