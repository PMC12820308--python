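"""Synthetic EHR heterogeneous graphs with planted disease structure.

Each simulated patient carries exactly one disease label.  Drug and
procedure event counts are Poisson-distributed (floored at one so nobody is
edgeless before noise); each event is drawn from the patient's
class-specific preferred subset with probability ``signal_strength`` and
uniformly otherwise.  Three noise channels emulate real-record corruption:
spurious patient-event edges added uniformly over non-edges, edges dropped
at random, and labels flipped to a random other class.  Label noise is
applied after edge generation, so the graph reflects the true class -- the
harder, diagnostic-label-error regime.

Everything is deterministic per seed; the ground-truth record preserves
the preferred subsets and pre-noise labels for test oracles.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .hetgraph import HetGraph, build_graph


@dataclass
class SyntheticSpec:
    n_patients: int = 600
    n_drugs: int = 90
    n_procedures: int = 45
    n_classes: int = 3
    drugs_per_patient_mean: float = 8.0
    procedures_per_patient_mean: float = 3.0
    signal_strength: float = 0.9
    preferred_set_size: Optional[int] = None   # default: n // (2 * classes)
    spurious_edge_rate: float = 0.05
    edge_dropout_rate: float = 0.05
    label_noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_patients < self.n_classes:
            raise ValueError("need at least one patient per class")
        for r in (self.signal_strength, self.spurious_edge_rate,
                  self.edge_dropout_rate, self.label_noise_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


def _preferred_sets(rng, n_items: int, n_classes: int,
                    size: int) -> List[np.ndarray]:
    """Per-class preferred item subsets, disjoint whenever they fit."""
    if n_classes * size <= n_items:
        perm = rng.permutation(n_items)
        return [perm[c * size : (c + 1) * size] for c in range(n_classes)]
    return [rng.choice(n_items, size=min(size, n_items), replace=False)
            for _ in range(n_classes)]


def _draw_events(rng, label: int, mean: float, n_items: int,
                 preferred: List[np.ndarray], signal: float) -> np.ndarray:
    count = max(1, int(rng.poisson(mean)))
    pref = preferred[label]
    if pref.size == 0 or signal <= 0.0:
        return np.unique(rng.integers(0, n_items, size=count))
    pref_draw = pref[rng.integers(0, pref.size, size=count)]
    uniform_draw = rng.integers(0, n_items, size=count)
    items = np.where(rng.random(count) < signal, pref_draw, uniform_draw)
    return np.unique(items)


def _apply_edge_noise(rng, edges: set, n_src: int, n_dst: int,
                      spurious_rate: float, dropout_rate: float) -> set:
    kept = {e for e in edges if rng.random() >= dropout_rate}
    free = n_src * n_dst - len(kept)
    n_spurious = min(int(round(spurious_rate * len(kept))), free)
    added = 0
    while added < n_spurious:
        e = (int(rng.integers(n_src)), int(rng.integers(n_dst)))
        if e not in kept:
            kept.add(e)
            added += 1
    return kept


def generate(
    spec: SyntheticSpec,
) -> Tuple[HetGraph, np.ndarray, Dict]:
    """Simulate a cohort; returns (graph, labels, ground-truth record)."""
    rng = np.random.default_rng(spec.seed)
    C = spec.n_classes
    size_d = spec.preferred_set_size or max(1, spec.n_drugs // (2 * C))
    size_o = spec.preferred_set_size or max(1, spec.n_procedures // (2 * C))

    # one class per patient; the first C (shuffled) patients guarantee that
    # every class is represented, the rest are uniform
    labels = rng.integers(0, C, size=spec.n_patients)
    first = rng.permutation(spec.n_patients)[:C]
    labels[first] = np.arange(C)

    pref_d = _preferred_sets(rng, spec.n_drugs, C, size_d)
    pref_o = _preferred_sets(rng, spec.n_procedures, C, size_o)

    pd_set, po_set = set(), set()
    for p in range(spec.n_patients):
        for d in _draw_events(rng, labels[p], spec.drugs_per_patient_mean,
                              spec.n_drugs, pref_d, spec.signal_strength):
            pd_set.add((p, int(d)))
        for o in _draw_events(rng, labels[p],
                              spec.procedures_per_patient_mean,
                              spec.n_procedures, pref_o,
                              spec.signal_strength):
            po_set.add((p, int(o)))

    pd_set = _apply_edge_noise(rng, pd_set, spec.n_patients, spec.n_drugs,
                               spec.spurious_edge_rate,
                               spec.edge_dropout_rate)
    po_set = _apply_edge_noise(rng, po_set, spec.n_patients,
                               spec.n_procedures,
                               spec.spurious_edge_rate,
                               spec.edge_dropout_rate)

    clean_labels = labels.copy()
    flip = rng.random(spec.n_patients) < spec.label_noise_rate
    for p in np.flatnonzero(flip):
        others = [c for c in range(C) if c != labels[p]]
        labels[p] = others[int(rng.integers(len(others)))]

    p_ids = [f"p{i:05d}" for i in range(spec.n_patients)]
    d_ids = [f"d{i:05d}" for i in range(spec.n_drugs)]
    o_ids = [f"o{i:05d}" for i in range(spec.n_procedures)]
    graph = build_graph(
        pd_edges=[(p_ids[p], d_ids[d]) for p, d in sorted(pd_set)],
        po_edges=[(p_ids[p], o_ids[o]) for p, o in sorted(po_set)],
        patient_ids=p_ids, drug_ids=d_ids, procedure_ids=o_ids,
    )
    truth = {
        "clean_labels": clean_labels,
        "preferred_drugs": pref_d,
        "preferred_procedures": pref_o,
        "flipped": np.flatnonzero(flip),
    }
    return graph, labels, truth


# ---------------------------------------------------------------------------
# plain-text dataset round-trip
def write_dataset(graph: HetGraph, labels, directory: str) -> None:
    """Write the cohort as CSV edge lists plus label and node tables."""
    os.makedirs(directory, exist_ok=True)
    ids = graph.node_ids_by_type
    for rel, fname in (("P-D", "pd_edges.csv"), ("P-O", "po_edges.csv")):
        s_t, d_t = rel.split("-")
        with open(os.path.join(directory, fname), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["src", "dst"])
            for i, j in graph.edges_by_relation[rel]:
                w.writerow([ids[s_t][i], ids[d_t][j]])
    with open(os.path.join(directory, "labels.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label"])
        for pid, y in zip(ids["P"], labels):
            w.writerow([pid, int(y)])
    with open(os.path.join(directory, "nodes.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "node_type"])
        for t in ("P", "D", "O"):
            for nid in ids[t]:
                w.writerow([nid, t])


def _read_csv(path: str, n_cols: int) -> List[List[str]]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) != n_cols:
            raise ValueError(f"malformed CSV {path}: bad header")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_cols or any(not c for c in row):
                raise ValueError(f"malformed CSV {path}: line {lineno}")
            rows.append(row)
    return rows


def read_dataset(directory: str) -> Tuple[HetGraph, np.ndarray]:
    """Inverse of :func:`write_dataset`; read(write(x)) is an identity."""
    pd_rows = _read_csv(os.path.join(directory, "pd_edges.csv"), 2)
    po_rows = _read_csv(os.path.join(directory, "po_edges.csv"), 2)
    label_rows = _read_csv(os.path.join(directory, "labels.csv"), 2)

    nodes_path = os.path.join(directory, "nodes.csv")
    kwargs = {}
    if os.path.exists(nodes_path):
        by_type: Dict[str, List[str]] = {"P": [], "D": [], "O": []}
        for nid, t in _read_csv(nodes_path, 2):
            if t not in by_type:
                raise ValueError(f"malformed CSV {nodes_path}: type {t!r}")
            by_type[t].append(nid)
        kwargs = dict(patient_ids=by_type["P"], drug_ids=by_type["D"],
                      procedure_ids=by_type["O"])
    else:
        kwargs = dict(patient_ids=[r[0] for r in label_rows])

    graph = build_graph(
        pd_edges=[tuple(r) for r in pd_rows],
        po_edges=[tuple(r) for r in po_rows],
        **kwargs,
    )
    label_of = {pid: int(y) for pid, y in label_rows}
    labels = np.array(
        [label_of[pid] for pid in graph.node_ids_by_type["P"]],
        dtype=np.int64,
    )
    return graph, labels
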