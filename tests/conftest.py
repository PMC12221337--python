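import dendropy
import numpy as np
import pandas as pd
import pytest

from sedibiome import CommunityTable, SimulationConfig, make_dataset


def parse_newick(s: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=s, schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def balanced_tree() -> dendropy.Tree:
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def toy_table() -> CommunityTable:
    counts = pd.DataFrame(
        [[5, 3, 0, 2], [0, 4, 6, 1], [7, 0, 1, 3]],
        index=["s1", "s2", "s3"], columns=["A", "B", "C", "D"],
    )
    return CommunityTable(counts)


@pytest.fixture(scope="session")
def selection_dataset():
    """One small selection-regime study reused by several suites."""
    cfg = SimulationConfig(n_taxa=80, n_samples=15, depth=4000,
                           regime="selection", seed=11)
    return make_dataset(cfg)


def random_community(rng: np.random.Generator, n_samples: int, n_otus: int,
                     lam: float = 5.0) -> CommunityTable:
    counts = rng.poisson(lam, size=(n_samples, n_otus))
    counts[:, 0] += 1  # keep every sample non-empty
    return CommunityTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"OTU_{j+1}" for j in range(n_otus)]))
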