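import logging

import networkx as nx
import pytest

from isotarget.io import GeneModel
from isotarget.simulate import SyntheticConfig, simulate_dataset

logging.getLogger("isotarget").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def tiny_model() -> GeneModel:
    """Three genes: g1 MIT (2 isoforms), g2 SIT, g3 MIT (3 isoforms)."""
    return GeneModel.from_records(
        [("g1", "i1"), ("g1", "i2"), ("g2", "i3"), ("g3", "i4"), ("g3", "i5"), ("g3", "i6")]
    )


@pytest.fixture(scope="session")
def synthetic_ds():
    """One full synthetic dataset at the default configuration (seed 11)."""
    return simulate_dataset(SyntheticConfig(seed=11))


@pytest.fixture()
def path_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edge("a", "b", weight=0.8)
    g.add_edge("b", "c", weight=0.7)
    return g
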