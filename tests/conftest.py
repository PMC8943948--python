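import numpy as np
import pytest

import iegnet as ig


@pytest.fixture
def small_table():
    """7-animal, 2-IEG, single-group count table with reproducible values."""
    rng = np.random.default_rng(42)
    records = []
    for a in range(1, 8):
        for ieg in ig.IEGS:
            for region in ig.REGIONS:
                records.append((f"NPA{a:02d}", "NPA", region, ieg,
                                float(rng.uniform(50, 150))))
    return ig.data_model.from_records(records)


@pytest.fixture
def cohort_table():
    """Full default synthetic cohort (4 x 7 animals), fixed seed."""
    return ig.simulate_counts(ig.default_paper_spec(seed=7))


@pytest.fixture
def two_cliques():
    """Unit-weight adjacency of two disconnected 3-cliques."""
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        W[a, b] = W[b, a] = 1.0
    return W
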