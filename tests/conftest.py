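import numpy as np
import pandas as pd
import pytest

from bovpop.genotype_io import GenotypeDataset


def make_dataset(calls, positions=None, chromosome="1", populations=None, years=None,
                 a1="A", a2="G"):
    """Small hand-rolled dataset from a calls matrix (lists allowed)."""
    calls = np.asarray(calls, dtype=np.uint8)
    n, m = calls.shape
    if positions is None:
        positions = [(j + 1) * 10_000 for j in range(m)]
    chroms = [chromosome] * m if isinstance(chromosome, str) else list(chromosome)
    a1s = [a1] * m if isinstance(a1, str) else list(a1)
    a2s = [a2] * m if isinstance(a2, str) else list(a2)
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j + 1}" for j in range(m)],
            "chromosome": chroms,
            "position_bp": positions,
            "allele_a1": a1s,
            "allele_a2": a2s,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i + 1}" for i in range(n)],
            "population": populations if populations is not None else ["P1"] * n,
            "birth_year": pd.array(years if years is not None else [pd.NA] * n, dtype="Int64"),
        }
    )
    return GenotypeDataset(samples, markers, calls)


@pytest.fixture
def toy_dataset():
    """4 samples x 5 markers with a missing call and mixed genotypes."""
    return make_dataset(
        [
            [0, 1, 2, 1, 0],
            [1, 1, 2, 0, 0],
            [2, 0, 2, 3, 1],  # one missing call (code 3)
            [0, 2, 2, 2, 1],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_additive_tree_distances(n_taxa, rng):
    """Leaf-to-leaf distances of a random additive (tree-metric) topology.

    Builds a random unrooted binary tree by splitting random edges, then
    returns exact path-length distances — the oracle for NJ recovery.
    """
    import networkx as nx

    G = nx.Graph()
    G.add_edge("L0", "I0", w=rng.uniform(0.1, 1.0))
    G.add_edge("I0", "L1", w=rng.uniform(0.1, 1.0))
    G.add_edge("I0", "L2", w=rng.uniform(0.1, 1.0))
    leaves = ["L0", "L1", "L2"]
    for k in range(3, n_taxa):
        edges = list(G.edges())
        u, v = edges[rng.integers(len(edges))]
        w = G[u][v]["w"]
        G.remove_edge(u, v)
        mid = f"I{k}"
        frac = rng.uniform(0.2, 0.8)
        G.add_edge(u, mid, w=w * frac)
        G.add_edge(mid, v, w=w * (1.0 - frac))
        leaf = f"L{k}"
        G.add_edge(mid, leaf, w=rng.uniform(0.1, 1.0))
        leaves.append(leaf)
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="w"))
    D = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i != j:
                D[i, j] = lengths[a][b]
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    return pd.DataFrame(D, index=leaves, columns=leaves)
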