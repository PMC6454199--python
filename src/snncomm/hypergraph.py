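"""Hypergraph view of a spiking network and partition-quality metrics.

A spiking network maps onto a hypergraph H = (V, E): one vertex per neuron,
and one hyperedge per presynaptic neuron with at least one target, containing
that neuron together with all of its postsynaptic targets.  The hyperedge is
the unit of spike communication — when a neuron fires, every member of its
hyperedge must learn about it — so the number of parts a hyperedge touches,
minus one, is the communication price of an allocation.  Vertices are
weighted by in-degree + 1 (synapse objects live on the postsynaptic side, so
dendritic input is the dominant per-neuron workload).

The module also derives the Process Communication Graph (PCG): processes as
nodes, a directed edge a→b wherever at least one synapse crosses from a
neuron hosted on a to a neuron hosted on b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import Network

__all__ = [
    "Hypergraph",
    "Assignment",
    "PartitionMetrics",
    "PCG",
    "network_to_hypergraph",
    "vertex_weight",
    "vertex_weights",
    "partition_cost",
    "partition_imbalance",
    "partition_metrics",
    "build_pcg",
    "write_hmetis",
    "read_hmetis",
]


@dataclass
class Hypergraph:
    """Vertex-weighted hypergraph in CSR (pin-list) form.

    ``eptr``/``pins`` store hyperedges back to back: hyperedge ``e`` is
    ``pins[eptr[e]:eptr[e+1]]``.  Hyperedges are non-empty vertex sets (no
    duplicate pins within an edge) and weights are >= 1.
    """

    n_vertices: int
    vertex_weights: np.ndarray  # int64, shape (n_vertices,)
    eptr: np.ndarray            # int64, shape (n_edges + 1,)
    pins: np.ndarray            # int64, shape (n_pins,)

    def __post_init__(self):
        self.vertex_weights = np.asarray(self.vertex_weights, dtype=np.int64)
        self.eptr = np.asarray(self.eptr, dtype=np.int64)
        self.pins = np.asarray(self.pins, dtype=np.int64)
        if len(self.vertex_weights) != self.n_vertices:
            raise ValueError("vertex_weights length mismatch")
        if len(self.pins) and (
            self.pins.min() < 0 or self.pins.max() >= self.n_vertices
        ):
            raise ValueError("pin out of range")
        if np.any(np.diff(self.eptr) < 1):
            raise ValueError("empty hyperedge")
        if self.n_vertices and self.vertex_weights.min() < 1:
            raise ValueError("vertex weights must be >= 1")

    @property
    def n_edges(self) -> int:
        return len(self.eptr) - 1

    @property
    def n_pins(self) -> int:
        return int(len(self.pins))

    def edge_sizes(self) -> np.ndarray:
        return np.diff(self.eptr)

    def edge(self, e: int) -> np.ndarray:
        return self.pins[self.eptr[e]:self.eptr[e + 1]]

    def hyperedges(self) -> list[np.ndarray]:
        return [self.edge(e) for e in range(self.n_edges)]

    def total_weight(self) -> int:
        return int(self.vertex_weights.sum())

    @classmethod
    def from_edge_lists(cls, n_vertices, hyperedges, vertex_weights=None):
        """Build from an iterable of vertex collections (deduplicated)."""
        edges = [np.unique(np.asarray(e, dtype=np.int64)) for e in hyperedges]
        edges = [e for e in edges if len(e) > 0]
        eptr = np.zeros(len(edges) + 1, dtype=np.int64)
        if edges:
            np.cumsum([len(e) for e in edges], out=eptr[1:])
            pins = np.concatenate(edges)
        else:
            pins = np.empty(0, dtype=np.int64)
        if vertex_weights is None:
            vertex_weights = np.ones(n_vertices, dtype=np.int64)
        return cls(n_vertices, vertex_weights, eptr, pins)

    def incidence(self) -> tuple[np.ndarray, np.ndarray]:
        """Vertex→edge CSR (transpose of the pin list)."""
        sizes = self.edge_sizes()
        edge_of_pin = np.repeat(np.arange(self.n_edges, dtype=np.int64), sizes)
        order = np.argsort(self.pins, kind="stable")
        vptr = np.zeros(self.n_vertices + 1, dtype=np.int64)
        np.cumsum(np.bincount(self.pins, minlength=self.n_vertices), out=vptr[1:])
        return vptr, edge_of_pin[order]


@dataclass
class Assignment:
    """Total map vertex → part id in [0, n_parts)."""

    parts: np.ndarray
    n_parts: int
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.parts = np.asarray(self.parts, dtype=np.int32)
        if self.n_parts < 1:
            raise ValueError("n_parts must be >= 1")
        if len(self.parts) and (
            self.parts.min() < 0 or self.parts.max() >= self.n_parts
        ):
            raise ValueError("part id out of range")

    def __len__(self) -> int:
        return len(self.parts)

    def part_loads(self, weights: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.parts, weights=np.asarray(weights, dtype=np.float64),
            minlength=self.n_parts,
        )

    def part_sizes(self) -> np.ndarray:
        return np.bincount(self.parts, minlength=self.n_parts)


@dataclass
class PartitionMetrics:
    cut_cost: int
    part_loads: np.ndarray
    imbalance: float


@dataclass
class PCG:
    """Process Communication Graph with crossing-synapse annotations."""

    n_processes: int
    edge_src: np.ndarray        # int32
    edge_dst: np.ndarray        # int32
    crossing_counts: np.ndarray  # int64, synapses crossing each edge
    hosted: np.ndarray          # int64, neurons per process

    @property
    def n_edges(self) -> int:
        return int(len(self.edge_src))

    def density(self) -> np.ndarray:
        """Connection density per edge: crossings / (N_a * N_b)."""
        na = self.hosted[self.edge_src].astype(np.float64)
        nb = self.hosted[self.edge_dst].astype(np.float64)
        return self.crossing_counts / (na * nb)

    def out_neighbors(self, p: int) -> np.ndarray:
        return self.edge_dst[self.edge_src == p]


# ---------------------------------------------------------------------------


def _check_cover(n_vertices: int, a: Assignment) -> None:
    if len(a.parts) != n_vertices:
        raise ValueError(
            f"assignment covers {len(a.parts)} vertices, hypergraph has "
            f"{n_vertices}"
        )


def network_to_hypergraph(net: Network) -> Hypergraph:
    """One hyperedge per presynaptic neuron with out-degree >= 1.

    The hyperedge holds the presynaptic neuron itself plus the distinct set
    of its postsynaptic targets (multiple synapses onto the same target
    contribute a single pin: one spike message per target regardless of
    synapse multiplicity).
    """
    n = net.n_neurons
    out_deg = net.out_degree()
    senders = np.flatnonzero(out_deg > 0)
    if len(senders) == 0:
        return Hypergraph(
            n, vertex_weights(net), np.zeros(1, dtype=np.int64),
            np.empty(0, dtype=np.int64),
        )
    # pins = targets plus the presynaptic vertex itself, deduplicated per edge
    edge_index = np.zeros(n, dtype=np.int64)
    edge_index[senders] = np.arange(len(senders))
    pin_edge = np.concatenate(
        [edge_index[net.pre_ids()], np.arange(len(senders), dtype=np.int64)]
    )
    pin_vert = np.concatenate([net.post_ids, senders.astype(np.int64)])
    key = pin_edge * np.int64(n) + pin_vert
    uniq = np.unique(key)
    e = uniq // n
    v = uniq % n
    eptr = np.zeros(len(senders) + 1, dtype=np.int64)
    np.cumsum(np.bincount(e, minlength=len(senders)), out=eptr[1:])
    return Hypergraph(n, vertex_weights(net), eptr, v)


def vertex_weights(net: Network) -> np.ndarray:
    """Workload weight of every neuron: in-degree + 1."""
    return net.in_degree() + 1


def vertex_weight(net: Network, neuron: int) -> int:
    """Workload weight of one neuron (in-degree + 1)."""
    if not 0 <= neuron < net.n_neurons:
        raise IndexError(f"neuron {neuron} out of range [0, {net.n_neurons})")
    return int((net.post_ids == neuron).sum()) + 1


def edge_part_counts(hg: Hypergraph, a: Assignment) -> np.ndarray:
    """(n_edges, n_parts) matrix of pins per part — the FM bookkeeping."""
    counts = np.zeros((hg.n_edges, a.n_parts), dtype=np.int32)
    if hg.n_pins:
        edge_of_pin = np.repeat(
            np.arange(hg.n_edges, dtype=np.int64), hg.edge_sizes()
        )
        np.add.at(counts, (edge_of_pin, a.parts[hg.pins]), 1)
    return counts


def partition_cost(hg: Hypergraph, a: Assignment) -> int:
    """Connectivity-1 cut: sum over hyperedges of (parts touched − 1)."""
    _check_cover(hg.n_vertices, a)
    if hg.n_edges == 0:
        return 0
    edge_of_pin = np.repeat(np.arange(hg.n_edges, dtype=np.int64), hg.edge_sizes())
    key = edge_of_pin * np.int64(a.n_parts) + a.parts[hg.pins]
    distinct_pairs = len(np.unique(key))
    return int(distinct_pairs - hg.n_edges)


def partition_imbalance(hg: Hypergraph, a: Assignment) -> float:
    """Max part load over mean part load (loads from vertex weights)."""
    _check_cover(hg.n_vertices, a)
    loads = a.part_loads(hg.vertex_weights)
    mean = loads.sum() / a.n_parts
    if mean == 0:
        return 1.0
    return float(loads.max() / mean)


def partition_metrics(hg: Hypergraph, a: Assignment) -> PartitionMetrics:
    return PartitionMetrics(
        cut_cost=partition_cost(hg, a),
        part_loads=a.part_loads(hg.vertex_weights),
        imbalance=partition_imbalance(hg, a),
    )


def build_pcg(net: Network, a: Assignment) -> PCG:
    """Directed process graph: edge a→b iff any synapse crosses a→b."""
    _check_cover(net.n_neurons, a)
    P = a.n_parts
    src = a.parts[net.pre_ids()].astype(np.int64)
    dst = a.parts[net.post_ids].astype(np.int64)
    cross = src != dst
    key = src[cross] * P + dst[cross]
    uniq, counts = np.unique(key, return_counts=True)
    return PCG(
        n_processes=P,
        edge_src=(uniq // P).astype(np.int32),
        edge_dst=(uniq % P).astype(np.int32),
        crossing_counts=counts.astype(np.int64),
        hosted=a.part_sizes().astype(np.int64),
    )


# ---------------------------------------------------------------------------
# hMETIS-style text interchange
# ---------------------------------------------------------------------------

def write_hmetis(hg: Hypergraph, path) -> None:
    """hMETIS format with vertex weights (fmt code 10, 1-based vertex ids)."""
    with open(Path(path), "w") as fh:
        fh.write(f"{hg.n_edges} {hg.n_vertices} 10\n")
        for e in range(hg.n_edges):
            fh.write(" ".join(str(v + 1) for v in hg.edge(e)) + "\n")
        for w in hg.vertex_weights:
            fh.write(f"{w}\n")


def read_hmetis(path) -> Hypergraph:
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("%")
    ]
    head = lines[0].split()
    n_edges, n_vertices = int(head[0]), int(head[1])
    fmt = head[2] if len(head) > 2 else "0"
    edges = [
        np.asarray(lines[1 + e].split(), dtype=np.int64) - 1
        for e in range(n_edges)
    ]
    if fmt in ("10", "11"):
        w = np.asarray(lines[1 + n_edges:1 + n_edges + n_vertices], dtype=np.int64)
    else:
        w = np.ones(n_vertices, dtype=np.int64)
    return Hypergraph.from_edge_lists(n_vertices, edges, w)
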