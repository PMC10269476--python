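import numpy as np
import pytest

from repliscope import (FeatureTable, ReplicateDesign, SyntheticConfig,
                        simulate_study)


@pytest.fixture
def tiny_table():
    """Two samples x two replicates over four features, hand-written."""
    counts = np.array([
        [50, 30, 20, 0],
        [40, 10, 0, 50],
        [5, 0, 90, 5],
        [0, 2, 80, 18],
    ])
    return FeatureTable(["S1a", "S1b", "S2a", "S2b"],
                        ["f1", "f2", "f3", "f4"], counts)


@pytest.fixture
def tiny_design():
    return ReplicateDesign({"S1": ["S1a", "S1b"], "S2": ["S2a", "S2b"]})


@pytest.fixture
def identical_replicates():
    """Three samples, three identical replicates each; samples distinct."""
    rows, rids, groups = [], [], {}
    # equal library sizes, so rarefaction to the minimum depth is an identity
    base = [[100, 50, 10, 0, 3], [5, 80, 40, 20, 18], [1, 1, 121, 31, 9]]
    for s, vec in enumerate(base, 1):
        sid = f"S{s}"
        groups[sid] = []
        for r in range(3):
            rid = f"{sid}r{r + 1}"
            rids.append(rid)
            rows.append(vec)
            groups[sid].append(rid)
    table = FeatureTable(rids, [f"f{j}" for j in range(5)], np.array(rows))
    return table, ReplicateDesign(groups)


@pytest.fixture(scope="session")
def small_study():
    """A small default-noise synthetic study shared across tests."""
    cfg = SyntheticConfig(n_samples=12, depth_range=(3000, 3000), seed=101)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The calibrated study condition: 50 samples x 3 replicates, depth 20k."""
    cfg = SyntheticConfig(n_samples=50, depth_range=(20000, 20000), seed=202)
    return simulate_study(cfg)
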