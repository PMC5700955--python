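"""Numba quadtree for the Barnes-Hut approximation of t-SNE repulsion.

The repulsive part of the t-SNE gradient sums Student-t kernel forces over
all point pairs; a quadtree summarises distant groups of points by their
centre of mass whenever ``side / distance < theta``, reducing the cost per
iteration from O(n^2) to O(n log n).  Coincident points are merged into one
leaf with integer mass, so degenerate configurations cannot recurse forever.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EMPTY = np.int64(-1)


@njit
def _build_tree(pos, child, center, half, cum_count, cum_com, mass):
    n = pos.shape[0]
    xmin = pos[:, 0].min()
    xmax = pos[:, 0].max()
    ymin = pos[:, 1].min()
    ymax = pos[:, 1].max()
    cx = 0.5 * (xmin + xmax)
    cy = 0.5 * (ymin + ymax)
    h = 0.5 * max(xmax - xmin, ymax - ymin) * 1.0001 + 1e-12
    center[0, 0] = cx
    center[0, 1] = cy
    half[0] = h
    next_free = 1
    for p in range(n):
        if mass[p] == 0.0:
            continue  # merged duplicate
        node = 0
        while True:
            cum_count[node] += mass[p]
            cum_com[node, 0] += mass[p] * pos[p, 0]
            cum_com[node, 1] += mass[p] * pos[p, 1]
            qx = 1 if pos[p, 0] >= center[node, 0] else 0
            qy = 1 if pos[p, 1] >= center[node, 1] else 0
            q = 2 * qy + qx
            slot = child[node, q]
            if slot == _EMPTY:
                child[node, q] = -(p + 2)
                break
            if slot <= -2:  # occupied by a leaf point
                other = -(slot + 2)
                same = (pos[other, 0] == pos[p, 0]) and (pos[other, 1] == pos[p, 1])
                if same or half[node] < 1e-10:
                    mass[other] += mass[p]
                    mass[p] = 0.0
                    break
                # split: allocate an internal node and push the old leaf down
                if next_free >= child.shape[0]:
                    return -1
                new = next_free
                next_free += 1
                hh = 0.5 * half[node]
                center[new, 0] = center[node, 0] + (hh if qx == 1 else -hh)
                center[new, 1] = center[node, 1] + (hh if qy == 1 else -hh)
                half[new] = hh
                child[node, q] = new
                oqx = 1 if pos[other, 0] >= center[new, 0] else 0
                oqy = 1 if pos[other, 1] >= center[new, 1] else 0
                child[new, 2 * oqy + oqx] = -(other + 2)
                cum_count[new] += mass[other]
                cum_com[new, 0] += mass[other] * pos[other, 0]
                cum_com[new, 1] += mass[other] * pos[other, 1]
                node = new
            else:
                node = slot
    return next_free


@njit
def _repulsion(pos, theta, child, center, half, cum_count, cum_com, mass, force, zper):
    n = pos.shape[0]
    theta2 = theta * theta
    stack = np.empty(4096, dtype=np.int64)
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        fx = 0.0
        fy = 0.0
        z = 0.0
        top = 0
        stack[top] = 0
        top += 1
        while top > 0:
            top -= 1
            code = stack[top]
            if code <= -2:  # leaf point
                j = -(code + 2)
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                d2 = dx * dx + dy * dy
                m = mass[j]
                if j == i or d2 == 0.0:
                    m -= 1.0  # exclude self from its own (possibly merged) leaf
                    if m <= 0.0:
                        continue
                q = 1.0 / (1.0 + d2)
                z += m * q
                fx += m * q * q * dx
                fy += m * q * q * dy
                continue
            node = code
            if cum_count[node] == 0.0:
                continue
            comx = cum_com[node, 0] / cum_count[node]
            comy = cum_com[node, 1] / cum_count[node]
            dx = xi - comx
            dy = yi - comy
            d2 = dx * dx + dy * dy
            side = 2.0 * half[node]
            if side * side < theta2 * d2:  # far enough: summarise the cell
                q = 1.0 / (1.0 + d2)
                c = cum_count[node]
                z += c * q
                fx += c * q * q * dx
                fy += c * q * q * dy
            else:
                for q4 in range(4):
                    slot = child[node, q4]
                    if slot != _EMPTY:
                        stack[top] = slot
                        top += 1
        force[i, 0] = fx
        force[i, 1] = fy
        zper[i] = z
    return 0


def barnes_hut_repulsion(pos: np.ndarray, theta: float) -> tuple[np.ndarray, float]:
    """Unnormalised repulsive forces and the Student-t partition sum.

    Returns ``(F, Z)`` with ``F[i] = sum_j m_j q_ij^2 (y_i - y_j)`` and
    ``Z = sum_{i != j} q_ij`` where ``q_ij = 1 / (1 + |y_i - y_j|^2)``.
    """
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    n = pos.shape[0]
    cap = 8 * n + 64
    while True:
        child = np.full((cap, 4), _EMPTY, dtype=np.int64)
        center = np.zeros((cap, 2))
        half = np.zeros(cap)
        cum_count = np.zeros(cap)
        cum_com = np.zeros((cap, 2))
        mass = np.ones(n)
        used = _build_tree(pos, child, center, half, cum_count, cum_com, mass)
        if used >= 0:
            break
        cap *= 2
    force = np.zeros((n, 2))
    zper = np.zeros(n)
    _repulsion(pos, theta, child, center, half, cum_count, cum_com, mass, force, zper)
    return force, float(zper.sum())
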