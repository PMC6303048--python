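import numpy as np
import pytest

import barcodegap as bg


@pytest.fixture(scope="session")
def sim5():
    """Small well-separated 5-species dataset used across modules."""
    cfg = bg.SimulationConfig(n_species=5, seed=11)
    return bg.simulate(cfg)


@pytest.fixture(scope="session")
def sim5_distances(sim5):
    aln, tax, truth = sim5
    return bg.distance_matrix(aln)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths and its
    additive (path-length) distance matrix — the NJ recovery oracle.

    Built by starting from a 3-leaf star and attaching each new leaf to
    a uniformly chosen existing edge; distances are accumulated
    independently of any NJ code via explicit path lengths.
    """
    # adjacency: node -> list of (neighbor, length); leaves 0..n-1
    names = [f"T{i}" for i in range(n_taxa)]
    edges: dict[int, dict[int, float]] = {}

    def add_edge(a, b, w):
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    def blen():
        return float(rng.uniform(0.5, 3.0))

    nxt = n_taxa  # internal node ids
    add_edge(0, nxt, blen())
    add_edge(1, nxt, blen())
    add_edge(2, nxt, blen())
    nxt += 1
    for leaf in range(3, n_taxa):
        pairs = [(a, b) for a in edges for b in edges[a] if a < b]
        a, b = pairs[int(rng.integers(0, len(pairs)))]
        w = edges[a].pop(b)
        edges[b].pop(a)
        split = float(rng.uniform(0.2, 0.8)) * w
        mid = nxt
        nxt += 1
        add_edge(a, mid, split)
        add_edge(b, mid, w - split)
        add_edge(leaf, mid, blen())

    # all-pairs leaf distances by BFS from each leaf
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]
    D = (D + D.T) / 2.0  # remove float asymmetry from per-leaf BFS sums
    return bg.DistanceMatrix(names, D, np.full((n_taxa, n_taxa), -1.0))
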