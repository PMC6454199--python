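"""Numba kernels for the multilevel partitioner's hot loops.

Everything here operates on flat CSR arrays; all randomness (visit orders)
is decided by the caller so the kernels are pure functions of their inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["match_pass", "fm_pass", "best_rebalance_move", "apply_move"]


@njit(cache=True)
def match_pass(vptr, vedges, eptr, pins, inv_em1, weights, order):
    """One level of agglomerative inner-product matching.

    Vertices are visited in ``order``; an unmatched vertex u is paired with
    the unmatched neighbor v maximizing sum over shared hyperedges of
    1/(|e|-1), ties broken by smaller combined weight then lower id.
    Returns (match, ops): match[u] is u's partner (or u itself), ops the
    number of score accumulations performed.
    """
    n = len(vptr) - 1
    match = np.full(n, -1, dtype=np.int64)
    score = np.zeros(n, dtype=np.float64)
    stamp = np.full(n, -1, dtype=np.int64)
    ops = 0
    for idx in range(n):
        u = order[idx]
        if match[u] >= 0:
            continue
        best = -1
        best_score = 0.0
        best_w = np.int64(0)
        for k in range(vptr[u], vptr[u + 1]):
            e = vedges[k]
            s = inv_em1[e]
            for t in range(eptr[e], eptr[e + 1]):
                v = pins[t]
                if v == u or match[v] >= 0:
                    continue
                if stamp[v] != u:
                    stamp[v] = u
                    score[v] = 0.0
                score[v] += s
                ops += 1
                sv = score[v]
                wv = weights[u] + weights[v]
                if best < 0 or sv > best_score or (
                    sv == best_score
                    and (wv < best_w or (wv == best_w and v < best))
                ):
                    best = v
                    best_score = sv
                    best_w = wv
        if best >= 0:
            match[u] = best
            match[best] = u
        else:
            match[u] = u
    return match, ops


@njit(cache=True)
def fm_pass(vptr, vedges, counts, parts, loads, weights, part_sizes,
            max_load, order):
    """One FM pass with rollback to the best prefix.

    Each vertex in ``order`` (the boundary, in a seeded random order) is
    tentatively moved to its gain-maximal admissible part and locked; at the
    end the pass rolls back to the prefix of moves with the best cumulative
    gain.  A move is admissible if the target load stays within ``max_load``
    and the source part keeps at least one vertex.  Gain is the reduction in
    connectivity-1 cost.  ``counts``/``parts``/``loads``/``part_sizes`` are
    updated in place.  Returns (net_gain, n_accepted_moves, n_tentative).
    """
    P = counts.shape[1]
    n_ord = len(order)
    moves_v = np.empty(n_ord, dtype=np.int64)
    moves_from = np.empty(n_ord, dtype=np.int32)
    moves_to = np.empty(n_ord, dtype=np.int32)
    conn = np.zeros(P, dtype=np.int64)
    n_moves = 0
    best_prefix = 0
    best_gain = np.int64(0)
    cum_gain = np.int64(0)
    for idx in range(n_ord):
        v = order[idx]
        a = parts[v]
        if part_sizes[a] <= 1:
            continue
        deg = vptr[v + 1] - vptr[v]
        if deg == 0:
            continue
        for b in range(P):
            conn[b] = 0
        sole_a = np.int64(0)
        boundary = False
        for k in range(vptr[v], vptr[v + 1]):
            e = vedges[k]
            if counts[e, a] == 1:
                sole_a += 1
            for b in range(P):
                if counts[e, b] > 0:
                    conn[b] += 1
                    if b != a:
                        boundary = True
        if not boundary:
            continue
        w = weights[v]
        best_b = -1
        best_g = np.int64(-(1 << 60))
        for b in range(P):
            if b == a or loads[b] + w > max_load:
                continue
            g = sole_a - (deg - conn[b])
            if g > best_g:
                best_g = g
                best_b = b
        if best_b < 0:
            continue
        b = best_b
        for k in range(vptr[v], vptr[v + 1]):
            e = vedges[k]
            counts[e, a] -= 1
            counts[e, b] += 1
        loads[a] -= w
        loads[b] += w
        part_sizes[a] -= 1
        part_sizes[b] += 1
        parts[v] = b
        moves_v[n_moves] = v
        moves_from[n_moves] = a
        moves_to[n_moves] = b
        n_moves += 1
        cum_gain += best_g
        if cum_gain > best_gain:
            best_gain = cum_gain
            best_prefix = n_moves
    for m in range(n_moves - 1, best_prefix - 1, -1):
        v = moves_v[m]
        a = moves_from[m]
        b = moves_to[m]
        w = weights[v]
        for k in range(vptr[v], vptr[v + 1]):
            e = vedges[k]
            counts[e, b] -= 1
            counts[e, a] += 1
        loads[b] -= w
        loads[a] += w
        part_sizes[b] -= 1
        part_sizes[a] += 1
        parts[v] = a
    return best_gain, best_prefix, n_moves


@njit(cache=True)
def best_rebalance_move(vptr, vedges, counts, parts, weights, verts, a, b,
                        load_a, load_b):
    """Best vertex to shift from overloaded part a to part b.

    Only moves that strictly decrease part a's load below its current value
    while keeping b lighter than a's old load are considered; among those,
    the one with the highest connectivity-1 gain (ties: lower id) wins.
    Returns (vertex, gain) or (-1, 0).
    """
    best_v = np.int64(-1)
    best_g = np.int64(-(1 << 60))
    for i in range(len(verts)):
        v = verts[i]
        if parts[v] != a:
            continue
        w = weights[v]
        if load_b + w >= load_a:
            continue
        sole_a = np.int64(0)
        conn_b = np.int64(0)
        deg = vptr[v + 1] - vptr[v]
        for k in range(vptr[v], vptr[v + 1]):
            e = vedges[k]
            if counts[e, a] == 1:
                sole_a += 1
            if counts[e, b] > 0:
                conn_b += 1
        g = sole_a - (deg - conn_b)
        if g > best_g or (g == best_g and (best_v < 0 or v < best_v)):
            best_g = g
            best_v = v
    if best_v < 0:
        return np.int64(-1), np.int64(0)
    return best_v, best_g


@njit(cache=True)
def apply_move(vptr, vedges, counts, parts, loads, weights, part_sizes, v, b):
    """Move vertex v to part b, updating all bookkeeping in place."""
    a = parts[v]
    w = weights[v]
    for k in range(vptr[v], vptr[v + 1]):
        e = vedges[k]
        counts[e, a] -= 1
        counts[e, b] += 1
    loads[a] -= w
    loads[b] += w
    part_sizes[a] -= 1
    part_sizes[b] += 1
    parts[v] = b
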