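import io

import numpy as np
import pytest
import scipy.sparse as sp

from netprio import EvidenceNetwork, IntegratedNetwork, integrate, read_edge_list


def network_from_edges(edges, extra_nodes=()):
    """Build an IntegratedNetwork from (a, b[, w]) tuples plus optional
    isolated nodes."""
    cleaned = {}
    nodes = set(extra_nodes)
    for e in edges:
        a, b = e[0], e[1]
        w = e[2] if len(e) == 3 else 1.0
        key = (a, b) if a <= b else (b, a)
        cleaned[key] = max(cleaned.get(key, 0.0), w)
        nodes.update((a, b))
    node_index = sorted(nodes)
    pos = {n: i for i, n in enumerate(node_index)}
    n = len(node_index)
    rows, cols, data = [], [], []
    for (a, b), w in cleaned.items():
        rows += [pos[a], pos[b]]
        cols += [pos[b], pos[a]]
        data += [w, w]
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return IntegratedNetwork(node_index=node_index, adjacency=adj)


def random_er_network(n, p, rng):
    """Erdős–Rényi network with at least one edge, unit weights."""
    while True:
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(iu.size) < p
        if keep.any():
            break
    ids = [f"n{i:03d}" for i in range(n)]
    return network_from_edges(
        [(ids[i], ids[j]) for i, j in zip(iu[keep], ju[keep])],
        extra_nodes=ids,
    )


def evidence(source, edges):
    text = "\n".join(" ".join(str(f) for f in e) for e in edges)
    return read_edge_list(io.StringIO(text), source)


@pytest.fixture
def triangle():
    return network_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path_abc():
    return network_from_edges([("A", "B"), ("B", "C")])
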