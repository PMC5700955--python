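"""Numba kernels for Monte-Carlo random walks on sparse row-stochastic graphs.

Every node owns a counter-based RNG stream derived from the master seed and
its node id (splitmix64 key expansion feeding an xorshift64* stream), so walk
results are identical for a given seed regardless of execution order or
parallelism.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


@njit(inline="always")
def _splitmix64(x):
    x = (x + _GOLDEN) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(inline="always")
def _node_state(seed, node):
    s = _splitmix64(np.uint64(seed) ^ (np.uint64(node + 1) * _GOLDEN))
    if s == np.uint64(0):
        s = _GOLDEN
    return s


@njit(inline="always")
def _next_uniform(state):
    # xorshift64*; returns (new_state, double in [0, 1))
    x = state
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    y = (x * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x, (y >> np.uint64(11)) * 1.1102230246251565e-16


@njit(inline="always")
def _step(node, indptr, indices, cumprobs, u):
    lo = indptr[node]
    hi = indptr[node + 1]
    if hi == lo:
        return node  # dangling row: stay put
    last = hi - 1
    target = u * cumprobs[last]
    # first index with cumprobs[i] > target (bisect_right)
    while lo < hi:
        mid = (lo + hi) // 2
        if cumprobs[mid] <= target:
            lo = mid + 1
        else:
            hi = mid
    if lo > last:
        lo = last
    return indices[lo]


@njit
def endpoint_hits(indptr, indices, cumprobs, walk_length, n_walks, seed):
    """Tally endpoints of fixed-length random walks started from every node."""
    n = indptr.shape[0] - 1
    hits = np.zeros(n, dtype=np.int64)
    for start in range(n):
        state = _node_state(seed, start)
        for _ in range(n_walks):
            node = start
            for _ in range(walk_length):
                state, u = _next_uniform(state)
                node = _step(node, indptr, indices, cumprobs, u)
            hits[node] += 1
    return hits


@njit
def influence_endpoints(indptr, indices, cumprobs, landmark_col, n_walks, max_steps, max_restarts, seed):
    """Landmark-absorbed walks: endpoints of ``n_walks`` walks per node.

    ``landmark_col[v]`` is the landmark column index of node ``v`` or -1.
    A walk started at a landmark terminates immediately at itself.  Walks
    exceeding ``max_steps`` steps restart; a walk that fails ``max_restarts``
    consecutive restarts is recorded as -1 (the caller raises).

    Returns (endpoints (n, n_walks) int64, total restart count).
    """
    n = indptr.shape[0] - 1
    out = np.full((n, n_walks), -1, dtype=np.int64)
    restarts = 0
    for start in range(n):
        if landmark_col[start] >= 0:
            for w in range(n_walks):
                out[start, w] = landmark_col[start]
            continue
        state = _node_state(seed, start)
        for w in range(n_walks):
            done = False
            for _ in range(max_restarts + 1):
                node = start
                for _ in range(max_steps):
                    state, u = _next_uniform(state)
                    node = _step(node, indptr, indices, cumprobs, u)
                    if landmark_col[node] >= 0:
                        out[start, w] = landmark_col[node]
                        done = True
                        break
                if done:
                    break
                restarts += 1
            # failure leaves -1 in place
    return out, restarts
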