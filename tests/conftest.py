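"""Shared fixtures and graph builders."""

from __future__ import annotations

import numpy as np
import pytest

from coexnet import Network


def path_graph(n: int, prefix: str = "n") -> Network:
    net = Network()
    names = [f"{prefix}{i:02d}" for i in range(n)]
    for a, b in zip(names, names[1:]):
        net.add_edge(a, b, 0.9)
    return net


def star_graph(n_leaves: int) -> Network:
    net = Network()
    for i in range(n_leaves):
        net.add_edge("center", f"leaf{i:02d}", 0.8)
    return net


def complete_graph(n: int) -> Network:
    net = Network()
    names = [f"k{i:02d}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            net.add_edge(names[i], names[j], 0.7)
    return net


def cycle_graph(n: int) -> Network:
    net = Network()
    names = [f"c{i:02d}" for i in range(n)]
    for i in range(n):
        net.add_edge(names[i], names[(i + 1) % n], 0.6)
    return net


def random_graph(n: int, p: float, seed: int) -> Network:
    """Seeded Erdős–Rényi test graph with distinct edge weights."""
    rng = np.random.default_rng(seed)
    net = Network()
    names = [f"r{i:02d}" for i in range(n)]
    for name in names:
        net.add_node(name)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(names[i], names[j], float(rng.uniform(0.5, 1.0)))
    return net


def to_networkx(net: Network):
    """Convert to networkx for oracle comparisons (test-time only)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.nodes())
    for u, v, w in net.edges():
        g.add_edge(u, v, weight=w)
    return g


@pytest.fixture
def small_aligned():
    """A small aligned dataset with planted modules for correlation tests."""
    from coexnet import SyntheticSpec, align_strains, generate_dataset

    spec = SyntheticSpec(
        n_strains=60,
        n_transcripts=140,
        module_sizes=(30, 30, 30),
        loading=2.0,
        noise_sd=1.0,
        phenotyped_fraction=1.0,
        rng_seed=7,
    )
    expr, pheno, truth = generate_dataset(spec)
    return align_strains(expr, pheno), truth
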