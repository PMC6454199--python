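"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — per-edge Python sets, exhaustive
enumeration, closed-form integrals — and stays independent of the package's
vectorized code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_cut(hyperedges, parts) -> int:
    """Connectivity-1 cut by direct evaluation of the definition."""
    total = 0
    for e in hyperedges:
        touched = {int(parts[v]) for v in e}
        total += len(touched) - 1
    return total


def brute_imbalance(weights, parts, n_parts) -> float:
    """Max part load over mean part load, empty parts allowed."""
    loads = [0.0] * n_parts
    for v, p in enumerate(parts):
        loads[int(p)] += float(weights[v])
    mean = sum(loads) / n_parts
    return max(loads) / mean if mean else 1.0


def exhaustive_optimum(hyperedges, n_vertices, n_parts,
                       weights=None, max_imbalance=None) -> int:
    """Minimum connectivity-1 cut over all (optionally balance-feasible)
    non-empty-part assignments, by enumeration.  Exponential; tiny n only."""
    best = math.inf
    for assign in itertools.product(range(n_parts), repeat=n_vertices):
        if len(set(assign)) < n_parts:
            continue  # the partitioner never emits empty parts
        if max_imbalance is not None:
            if brute_imbalance(weights, assign, n_parts) > max_imbalance:
                continue
        best = min(best, brute_cut(hyperedges, assign))
    return int(best)


def random_hypergraph(rng, n_vertices, n_edges, max_edge_size=5,
                      max_weight=9):
    """Random small hypergraph as (edge list, weights)."""
    edges = []
    for _ in range(n_edges):
        size = int(rng.integers(1, max_edge_size + 1))
        size = min(size, n_vertices)
        edges.append(np.sort(rng.choice(n_vertices, size=size, replace=False)))
    weights = rng.integers(1, max_weight + 1, size=n_vertices).astype(np.int64)
    return edges, weights


def lif_closed_form(t, v0, v_rest, r_m, i_const, tau_m):
    """Membrane relaxation with constant current, threshold disabled."""
    v_inf = v_rest + r_m * i_const
    return v_inf + (v0 - v_inf) * math.exp(-t / tau_m)


def lif_period(v_reset, v_thresh, v_rest, r_m, i_const, tau_m, t_ref):
    """Inter-spike interval of a suprathreshold LIF: refractory plus the
    first-passage time from reset to threshold."""
    v_inf = v_rest + r_m * i_const
    if v_inf <= v_thresh:
        return math.inf
    return t_ref + tau_m * math.log((v_inf - v_reset) / (v_inf - v_thresh))
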