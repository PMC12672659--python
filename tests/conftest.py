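import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")

from patientnets.communities import BipartiteGraph, InteractionKey
from patientnets.harmonize import OmicsMatrix


def random_bipartite(rng, n_p=None, n_i=None, p_edge=0.5):
    """Small random patient--interaction graph with at least one edge."""
    n_p = n_p or int(rng.integers(2, 6))
    n_i = n_i or int(rng.integers(2, 7))
    while True:
        pats = [f"p{k}" for k in range(n_p)]
        ints = [InteractionKey(f"s{k}", 1, f"t{k}") for k in range(n_i)]
        adj = {p: {i for i in ints if rng.random() < p_edge} for p in pats}
        if sum(len(s) for s in adj.values()) > 0:
            return BipartiteGraph(pats, ints, adj)


def block_bipartite(n_per_side: int, n_blocks: int = 2) -> BipartiteGraph:
    """Disjoint complete K_{n,n} blocks (the planted optimum is the blocks)."""
    pats, ints, adj = [], [], {}
    for b in range(n_blocks):
        bp = [f"b{b}p{k}" for k in range(n_per_side)]
        bi = [InteractionKey(f"b{b}s{k}", 1, f"b{b}t{k}") for k in range(n_per_side)]
        pats += bp
        ints += bi
        for p in bp:
            adj[p] = set(bi)
    return BipartiteGraph(pats, ints, adj)


@pytest.fixture
def proteomics_matrix():
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(10, 2, size=(20, 8)),
        index=[f"P{i}" for i in range(20)],
        columns=[f"S{i}" for i in range(8)],
    )
    data.iloc[0, 0] = np.nan
    data.iloc[3, 2:5] = np.nan
    return OmicsMatrix(data, "proteomics", "raw")


@pytest.fixture(scope="session")
def planted_cohort():
    """One planted cohort shared across tests (seed fixed)."""
    from patientnets.synthetic import generate_cohort

    return generate_cohort(seed=7)
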