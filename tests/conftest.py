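import numpy as np
import pytest

from netalign import Alignment, Network, SimilarityMatrix


def network_from_edges(ids, edges, directed=False, weights=None):
    """Small-network helper: build from a list of index pairs."""
    n = len(ids)
    adj = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        adj[i, j] = w
        if not directed:
            adj[j, i] = w
    kind = "binary" if weights is None else "continuous"
    return Network(list(ids), adj, directed=directed, weight_kind=kind)


@pytest.fixture
def ring6():
    """Two identical 6-vertex rings with an identity-like theta."""
    ids_g = [f"x{i}" for i in range(6)]
    ids_g2 = [f"y{i}" for i in range(6)]
    edges = [(i, (i + 1) % 6) for i in range(6)]
    g = network_from_edges(ids_g, edges)
    g2 = network_from_edges(ids_g2, edges)
    theta = SimilarityMatrix(
        ids_g, ids_g2, {(f"x{i}", f"y{i}"): 1.0 for i in range(6)}
    )
    return g, g2, theta


@pytest.fixture
def identity6(ring6):
    g, g2, _ = ring6
    return Alignment({i: j for i, j in zip(g.vertex_ids, g2.vertex_ids)})
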