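import numpy as np
import pytest

from lakeassembly import (
    AbundanceMatrix,
    NeutralSimConfig,
    simulate_neutral,
    simulate_tree,
)


@pytest.fixture(scope="session")
def small_tree():
    return simulate_tree(20, seed=11)


@pytest.fixture(scope="session")
def neutral_matrix():
    """Medium neutral community used by several calibration tests."""
    cfg = NeutralSimConfig(
        n_taxa=80, n_samples=25, community_size=2000, migration_rate=0.1, seed=42
    )
    return simulate_neutral(cfg)


@pytest.fixture()
def toy_matrix():
    counts = np.array(
        [
            [5, 0, 3, 0],
            [1, 2, 0, 0],
            [0, 7, 1, 4],
        ]
    )
    return AbundanceMatrix(counts, ["s1", "s2", "s3"], ["t1", "t2", "t3", "t4"])
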