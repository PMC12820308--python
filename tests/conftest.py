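"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hgdiag.hetgraph import HetGraph, MetaPath, build_graph


@pytest.fixture
def toy_graph() -> HetGraph:
    """p1,p2 share d1; p3 has d2; p1 has o1."""
    return build_graph(
        pd_edges=[("p1", "d1"), ("p2", "d1"), ("p3", "d2")],
        po_edges=[("p1", "o1")],
    )


@pytest.fixture
def chain_graph() -> HetGraph:
    """Path p1 - d1 - p2 - d2 - p3."""
    return build_graph(
        pd_edges=[("p1", "d1"), ("p2", "d1"), ("p2", "d2"), ("p3", "d2")],
        po_edges=[],
    )


def random_hetgraph(rng: np.random.Generator, max_nodes: int = 12,
                    transpose_consistent: bool = False) -> HetGraph:
    """Random small heterogeneous graph for property tests."""
    n_p = int(rng.integers(1, 6))
    n_d = int(rng.integers(0, 5))
    n_o = int(rng.integers(0, max(1, max_nodes - n_p - n_d)))
    p_ids = [f"p{i}" for i in range(n_p)]
    d_ids = [f"d{i}" for i in range(n_d)]
    o_ids = [f"o{i}" for i in range(n_o)]

    def edges(src, dst, p=0.4):
        return [(a, b) for a in src for b in dst if rng.random() < p]

    pd = edges(p_ids, d_ids)
    po = edges(p_ids, o_ids)
    if transpose_consistent:
        dp = [(b, a) for a, b in pd]
        op = [(b, a) for a, b in po]
    else:
        dp = edges(d_ids, p_ids)
        op = edges(o_ids, p_ids)
    return build_graph(pd, po, dp_edges=dp, op_edges=op,
                       patient_ids=p_ids, drug_ids=d_ids,
                       procedure_ids=o_ids)


def enumerate_walks(graph: HetGraph, path: MetaPath):
    """Brute-force ordered walks following a meta-path template.

    Yields tuples of local node indices; endpoints may coincide (callers
    filter).  Independent of the sparse-matrix composition code.
    """
    adj = {
        rel: {(i, j) for i, j in graph.edges_by_relation[rel]}
        for rel in graph.edges_by_relation
    }
    counts = [graph.num(t) for t in path.type_sequence]

    def extend(prefix):
        depth = len(prefix) - 1
        if depth == len(path.relation_sequence):
            yield tuple(prefix)
            return
        rel = path.relation_sequence[depth]
        for nxt in range(counts[depth + 1]):
            if (prefix[-1], nxt) in adj[rel]:
                yield from extend(prefix + [nxt])

    for start in range(counts[0]):
        yield from extend([start])


def brute_force_metapath_matrix(graph: HetGraph, path: MetaPath) -> np.ndarray:
    """0/1 patient-patient reachability by exhaustive walk enumeration."""
    n = graph.n_patients
    out = np.zeros((n, n), dtype=np.int8)
    for walk in enumerate_walks(graph, path):
        if walk[0] != walk[-1]:
            out[walk[0], walk[-1]] = 1
    return out


def brute_force_metapath_count(graph: HetGraph, path: MetaPath) -> int:
    return sum(
        1 for walk in enumerate_walks(graph, path) if walk[0] != walk[-1]
    )


def bfs_exact_khop(graph: HetGraph, start_unified: int, k: int) -> set:
    """Reference breadth-first exact-distance set on the union graph."""
    adj = graph.union_adjacency()
    n = adj.shape[0]
    dist = {start_unified: 0}
    frontier = [start_unified]
    depth = 0
    while frontier and depth < k:
        depth += 1
        nxt = []
        for u in frontier:
            for v in adj.indices[adj.indptr[u]:adj.indptr[u + 1]]:
                if v not in dist:
                    dist[v] = depth
                    nxt.append(v)
        frontier = nxt
    return {u for u, d in dist.items() if d == k}
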