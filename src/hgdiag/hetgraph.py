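"""Heterogeneous patient-drug-procedure graph model.

The electronic-health-record cohort is represented as a typed graph with
three node types -- patients (``P``), drugs (``D``) and procedures (``O``) --
and four directed relations (``P-D``, ``D-P``, ``P-O``, ``O-P``), each stored
as a binary sparse adjacency matrix.  Meta-paths (alternating type sequences
such as ``P-D-P``) act as semantic templates; their adjacency is the
binarized product of the relation matrices along the path.

Opposite relations are stored independently: real cohorts report unequal
directed edge counts for the two directions, so ``D-P`` need not equal the
transpose of ``P-D``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

NODE_TYPES = ("P", "D", "O")
RELATIONS = ("P-D", "D-P", "P-O", "O-P")

#: Relation implied by an ordered pair of node types.
_PAIR_TO_RELATION = {
    ("P", "D"): "P-D",
    ("D", "P"): "D-P",
    ("P", "O"): "P-O",
    ("O", "P"): "O-P",
}


@dataclass
class HetGraph:
    """Typed node universe plus one binary adjacency per directed relation."""

    node_ids_by_type: Dict[str, List[str]]
    edges_by_relation: Dict[str, List[Tuple[int, int]]]
    relation_adjacency: Dict[str, sp.csr_matrix]
    node_features: Optional[Dict[str, np.ndarray]] = None

    def num(self, node_type: str) -> int:
        return len(self.node_ids_by_type[node_type])

    @property
    def n_patients(self) -> int:
        return self.num("P")

    # ---- unified index space: patients first, then drugs, then procedures
    def type_offsets(self) -> Dict[str, int]:
        off, total = {}, 0
        for t in NODE_TYPES:
            off[t] = total
            total += self.num(t)
        return off

    @property
    def n_nodes(self) -> int:
        return sum(self.num(t) for t in NODE_TYPES)

    def unified_index(self, node_type: str, local_index: int) -> int:
        return self.type_offsets()[node_type] + local_index

    def type_of_unified(self, u: int) -> Tuple[str, int]:
        off = self.type_offsets()
        for t in reversed(NODE_TYPES):
            if u >= off[t]:
                return t, u - off[t]
        raise KeyError(f"node not found: {u}")

    def union_adjacency(self) -> sp.csr_matrix:
        """Undirected union of every relation in the unified index space."""
        n = self.n_nodes
        off = self.type_offsets()
        rows, cols = [], []
        for rel in RELATIONS:
            s_t, d_t = rel.split("-")
            a = self.relation_adjacency[rel].tocoo()
            rows.append(a.row + off[s_t])
            cols.append(a.col + off[d_t])
        r = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
        c = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
        m = sp.coo_matrix(
            (np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n)
        ).tocsr()
        m = ((m + m.T) > 0).astype(np.int8).tocsr()
        m.setdiag(0)
        m.eliminate_zeros()
        return m


@dataclass
class MetaPath:
    """Alternating node-type template starting and ending at a patient."""

    type_sequence: List[str]
    relation_sequence: List[str] = field(init=False)

    def __post_init__(self) -> None:
        seq = list(self.type_sequence)
        if len(seq) < 2 or seq[0] != "P" or seq[-1] != "P":
            raise ValueError("unsupported meta-path")
        rels = []
        for a, b in zip(seq, seq[1:]):
            if (a, b) not in _PAIR_TO_RELATION:
                raise ValueError("unsupported meta-path")
            rels.append(_PAIR_TO_RELATION[(a, b)])
        self.relation_sequence = rels

    @classmethod
    def from_string(cls, s: str) -> "MetaPath":
        return cls(type_sequence=s.split("-"))

    def __str__(self) -> str:
        return "-".join(self.type_sequence)


#: Meta-paths reported in cohort statistics.
PDP = MetaPath(["P", "D", "P"])
POP = MetaPath(["P", "O", "P"])
PDPOP = MetaPath(["P", "D", "P", "O", "P"])


@dataclass
class GraphStats:
    node_counts: Dict[str, int]
    edge_counts: Dict[str, int]
    metapath_instances: Dict[str, int]
    sparsity: float

    def to_dict(self) -> dict:
        return {
            "node_counts": dict(self.node_counts),
            "edge_counts": dict(self.edge_counts),
            "metapath_instances": dict(self.metapath_instances),
            "sparsity": float(self.sparsity),
        }


def build_graph(
    pd_edges: Sequence[Tuple[str, str]],
    po_edges: Sequence[Tuple[str, str]],
    dp_edges: Optional[Sequence[Tuple[str, str]]] = None,
    op_edges: Optional[Sequence[Tuple[str, str]]] = None,
    patient_ids: Optional[Sequence[str]] = None,
    drug_ids: Optional[Sequence[str]] = None,
    procedure_ids: Optional[Sequence[str]] = None,
) -> HetGraph:
    """Assemble a :class:`HetGraph` from edge lists.

    Node index spaces are the sorted unique identifiers of each type unless
    explicit id lists are supplied (needed to keep isolated nodes).
    Duplicate edge rows collapse to a single adjacency entry.  When the
    reverse relations are omitted they default to the transposes of the
    forward ones.
    """
    if dp_edges is None:
        dp_edges = [(d, p) for p, d in pd_edges]
    if op_edges is None:
        op_edges = [(o, p) for p, o in po_edges]

    def _ids(explicit, *cols):
        if explicit is not None:
            out = list(explicit)
            if len(set(out)) != len(out):
                raise ValueError("duplicate node identifiers")
            return sorted(out)
        seen: Set[str] = set()
        for col in cols:
            seen.update(col)
        return sorted(seen)

    p_ids = _ids(
        patient_ids,
        [e[0] for e in pd_edges],
        [e[0] for e in po_edges],
        [e[1] for e in dp_edges],
        [e[1] for e in op_edges],
    )
    d_ids = _ids(drug_ids, [e[1] for e in pd_edges], [e[0] for e in dp_edges])
    o_ids = _ids(procedure_ids, [e[1] for e in po_edges], [e[0] for e in op_edges])
    if not p_ids:
        raise ValueError("no patients")

    index = {
        "P": {v: i for i, v in enumerate(p_ids)},
        "D": {v: i for i, v in enumerate(d_ids)},
        "O": {v: i for i, v in enumerate(o_ids)},
    }
    nodes = {"P": p_ids, "D": d_ids, "O": o_ids}

    def _adj(edges, s_t, d_t):
        pairs = sorted(
            {(index[s_t][a], index[d_t][b]) for a, b in edges}
        )
        shape = (len(nodes[s_t]), len(nodes[d_t]))
        if not pairs:
            return [], sp.csr_matrix(shape, dtype=np.int8)
        r = np.array([p[0] for p in pairs])
        c = np.array([p[1] for p in pairs])
        m = sp.coo_matrix(
            (np.ones(len(pairs), dtype=np.int8), (r, c)), shape=shape
        ).tocsr()
        return pairs, m

    edges_by_relation, relation_adjacency = {}, {}
    for rel, edges, s_t, d_t in (
        ("P-D", pd_edges, "P", "D"),
        ("D-P", dp_edges, "D", "P"),
        ("P-O", po_edges, "P", "O"),
        ("O-P", op_edges, "O", "P"),
    ):
        pairs, m = _adj(edges, s_t, d_t)
        edges_by_relation[rel] = pairs
        relation_adjacency[rel] = m

    return HetGraph(nodes, edges_by_relation, relation_adjacency)


def _relation_product(graph: HetGraph, path: MetaPath) -> sp.csr_matrix:
    m = graph.relation_adjacency[path.relation_sequence[0]].astype(np.int64)
    for rel in path.relation_sequence[1:]:
        m = m @ graph.relation_adjacency[rel].astype(np.int64)
    return sp.csr_matrix(m)


def compose_metapath(graph: HetGraph, path: MetaPath) -> sp.csr_matrix:
    """Binary patient-patient adjacency induced by a meta-path.

    Entry (i, j) is 1 iff at least one walk follows the template from
    patient i to a *different* patient j; the diagonal is zeroed because an
    auxiliary subgraph links two distinct patients.
    """
    m = _relation_product(graph, path)
    m = (m > 0).astype(np.int8).tocsr()
    m.setdiag(0)
    m.eliminate_zeros()
    return m


def count_metapath_instances(graph: HetGraph, path: MetaPath) -> int:
    """Number of ordered template walks with distinct patient endpoints.

    Each intermediate-node choice is a distinct instance, so the count is
    the off-diagonal sum of the unbinarized relation-matrix product.
    """
    m = _relation_product(graph, path)
    return int(m.sum() - m.diagonal().sum())


def khop_levels(
    adj: sp.csr_matrix, start: int, k_max: int
) -> List[np.ndarray]:
    """Exact-distance BFS frontiers 1..k_max on a symmetric adjacency."""
    n = adj.shape[0]
    indptr, indices = adj.indptr, adj.indices
    visited = np.zeros(n, dtype=bool)
    visited[start] = True
    frontier = np.array([start], dtype=np.int64)
    levels: List[np.ndarray] = []
    for _ in range(k_max):
        if frontier.size == 0:
            levels.append(np.empty(0, dtype=np.int64))
            continue
        nxt = np.concatenate(
            [indices[indptr[u] : indptr[u + 1]] for u in frontier]
        )
        nxt = np.unique(nxt)
        nxt = nxt[~visited[nxt]]
        visited[nxt] = True
        levels.append(nxt)
        frontier = nxt
    return levels


def khop_neighborhood(graph: HetGraph, v: Tuple[str, int], k: int):
    """Nodes at shortest-path distance exactly ``k`` from ``v``.

    Distances are measured on the undirected union of all relations.
    ``v`` is a (node_type, local_index) reference; returns a set of the same
    references.
    """
    t, i = v
    if t not in NODE_TYPES or not (0 <= i < graph.num(t)):
        raise KeyError("node not found")
    if k < 1:
        raise ValueError("k must be >= 1")
    adj = graph.union_adjacency()
    levels = khop_levels(adj, graph.unified_index(t, i), k)
    return {graph.type_of_unified(int(u)) for u in levels[k - 1]}


def sparsity_from_counts(
    n_patients: int,
    n_drugs: int,
    n_procedures: int,
    e_pd: int,
    e_dp: int,
    e_po: int,
    e_op: int,
) -> float:
    """Bipartite edge density complement of the patient-event graph.

    ``1 - (E_PD + E_DP + E_PO + E_OP) / (2 |P| (|D| + |O|))`` -- the
    fraction of possible directed patient-to-event slots left empty.
    """
    denom = 2 * n_patients * (n_drugs + n_procedures)
    if denom == 0:
        warnings.warn("graph has no drug or procedure nodes; sparsity := 1")
        return 1.0
    return 1.0 - (e_pd + e_dp + e_po + e_op) / denom


def graph_stats(graph: HetGraph) -> GraphStats:
    """Cohort-level structural statistics (counts, meta-paths, sparsity)."""
    node_counts = {t: graph.num(t) for t in NODE_TYPES}
    edge_counts = {
        rel: int(graph.relation_adjacency[rel].sum()) for rel in RELATIONS
    }
    instances = {
        str(p): count_metapath_instances(graph, p) for p in (PDP, POP, PDPOP)
    }
    s = sparsity_from_counts(
        node_counts["P"],
        node_counts["D"],
        node_counts["O"],
        edge_counts["P-D"],
        edge_counts["D-P"],
        edge_counts["P-O"],
        edge_counts["O-P"],
    )
    return GraphStats(node_counts, edge_counts, instances, s)
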