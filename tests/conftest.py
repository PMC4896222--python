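import numpy as np
import pandas as pd
import pytest

from ssrmap import simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Structured 3-subpopulation panel with planted QTL, shared across tests."""
    cfg = simulate.default_config(seed=11, n_accessions=150, n_loci=24,
                                  n_subpops=3, fst=0.25, admixture_alpha=0.1)
    return simulate.simulate_dataset(cfg)


@pytest.fixture()
def toy_genotypes():
    """Hand-built 4x4 matrix with one null call."""
    return pd.DataFrame(
        {
            "L1": pd.array([120, 120, 124, pd.NA], dtype="Int64"),
            "L2": pd.array([200, 202, 200, 202], dtype="Int64"),
            "L3": pd.array([150, 150, 150, 150], dtype="Int64"),
            "L4": pd.array([90, 92, 94, 96], dtype="Int64"),
        },
        index=pd.Index(["a1", "a2", "a3", "a4"], name="accession"),
    )


@pytest.fixture()
def toy_phenotypes():
    rows = []
    for acc, base in [("a1", 6.0), ("a2", 8.0), ("a3", 10.0), ("a4", 12.0)]:
        for year in (2013, 2014):
            for rep in (1, 2):
                rows.append({"accession": acc, "trait": "GL", "year": year,
                             "replicate": rep, "value": base + 0.1 * rep})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def additive_matrix_factory():
    """Factory for random additive distance matrices with a tree-path oracle."""
    return random_additive_matrix


def random_additive_matrix(rng, n_taxa):
    """Distance matrix from a random binary tree with positive branch
    lengths, plus the taxon labels.  Path distances on the tree are the
    independent oracle for neighbor joining."""
    import itertools

    import networkx as nx

    g = nx.Graph()
    leaves = [f"t{i}" for i in range(n_taxa)]
    nodes = list(leaves)
    nxt = 0
    while len(nodes) > 2:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        parent = f"n{nxt}"
        nxt += 1
        g.add_edge(a, parent, weight=float(rng.uniform(0.5, 2.0)))
        g.add_edge(b, parent, weight=float(rng.uniform(0.5, 2.0)))
        nodes.append(parent)
    g.add_edge(nodes[0], nodes[1], weight=float(rng.uniform(0.5, 2.0)))
    d = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for a, b in itertools.combinations(leaves, 2):
        d.loc[a, b] = d.loc[b, a] = nx.shortest_path_length(g, a, b, weight="weight")
    return d
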