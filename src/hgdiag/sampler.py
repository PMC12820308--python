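"""Meta-path-guided fixed-width k-hop neighbor sampling.

For each patient in a mini-batch the sampler draws a fixed number of
neighbors (with replacement) from the exact-k-hop frontier for every hop
1..k_max, producing rectangular index arrays with validity masks.  Because
all edges connect patients to drugs or procedures, template-constrained
expansion (patients to events at odd hops, events back to patients at even
hops) coincides with plain shortest-path distance on the undirected union
graph, so the frontiers are the exact breadth-first levels.

Frontiers depend only on the graph and are cached once per graph; only the
draws change between epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .hetgraph import HetGraph, MetaPath, khop_levels


@dataclass
class SamplerConfig:
    k_max: int = 4
    per_hop: int = 32
    batch_size: int = 256
    templates: List[MetaPath] = field(
        default_factory=lambda: [
            MetaPath(["P", "D", "P"]),
            MetaPath(["P", "O", "P"]),
        ]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max < 1 or self.per_hop < 1 or self.batch_size < 1:
            raise ValueError("k_max, per_hop and batch_size must be >= 1")


@dataclass
class SampledBatch:
    """Fixed-width neighbor draws for a batch of patients.

    ``neighbor_indices`` live in the unified node index space (patients
    first, then drugs, then procedures); masked slots are padding.
    """

    patient_indices: np.ndarray          # (B,) patient local == unified idx
    neighbor_indices: np.ndarray         # (B, k_max, per_hop) int64
    neighbor_type: np.ndarray            # (B, k_max, per_hop) '<U1'
    mask: np.ndarray                     # (B, k_max, per_hop) bool


class KHopIndex:
    """Per-patient exact-k-hop frontier cache on the union graph."""

    def __init__(self, graph: HetGraph, k_max: int):
        self.graph = graph
        self.k_max = k_max
        adj = graph.union_adjacency()
        self.levels: List[List[np.ndarray]] = [
            khop_levels(adj, v, k_max) for v in range(graph.n_patients)
        ]
        off = graph.type_offsets()
        bounds = sorted((o, t) for t, o in off.items())
        self._bounds = bounds

    def type_codes(self, unified: np.ndarray) -> np.ndarray:
        out = np.full(unified.shape, "P", dtype="<U1")
        off = self.graph.type_offsets()
        n = {t: self.graph.num(t) for t in ("P", "D", "O")}
        for t in ("P", "D", "O"):
            lo, hi = off[t], off[t] + n[t]
            out[(unified >= lo) & (unified < hi)] = t
        return out


def sample_khop(
    index: KHopIndex, v: int, config: SamplerConfig, rng: np.random.Generator
) -> SampledBatch:
    """Sample one patient's hop-wise neighbor slots (a batch of size 1)."""
    if not (0 <= v < index.graph.n_patients):
        raise KeyError("node not found")
    k, s = config.k_max, config.per_hop
    idx = np.zeros((1, k, s), dtype=np.int64)
    mask = np.zeros((1, k, s), dtype=bool)
    for h in range(k):
        frontier = index.levels[v][h]
        if frontier.size == 0:
            continue
        idx[0, h] = rng.choice(frontier, size=s, replace=True)
        mask[0, h] = True
    return SampledBatch(
        patient_indices=np.array([v], dtype=np.int64),
        neighbor_indices=idx,
        neighbor_type=index.type_codes(idx),
        mask=mask,
    )


def _sample_rows(
    index: KHopIndex, patients: Sequence[int], config: SamplerConfig,
    rng: np.random.Generator
) -> SampledBatch:
    k, s = config.k_max, config.per_hop
    b = len(patients)
    idx = np.zeros((b, k, s), dtype=np.int64)
    mask = np.zeros((b, k, s), dtype=bool)
    for r, v in enumerate(patients):
        for h in range(k):
            frontier = index.levels[v][h]
            if frontier.size == 0:
                continue
            idx[r, h] = rng.choice(frontier, size=s, replace=True)
            mask[r, h] = True
    return SampledBatch(
        patient_indices=np.asarray(patients, dtype=np.int64),
        neighbor_indices=idx,
        neighbor_type=index.type_codes(idx),
        mask=mask,
    )


def make_batches(
    index: KHopIndex,
    patients: Sequence[int],
    config: SamplerConfig,
    rng: Optional[np.random.Generator] = None,
    shuffle: bool = True,
) -> List[SampledBatch]:
    """Shuffle, chunk into ``batch_size`` groups and materialize draws."""
    if len(patients) == 0:
        raise ValueError("patients must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    order = np.asarray(patients, dtype=np.int64)
    if shuffle:
        order = rng.permutation(order)
    return [
        _sample_rows(index, order[i : i + config.batch_size], config, rng)
        for i in range(0, len(order), config.batch_size)
    ]
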