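"""Barnes-Hut SNE embedding of a level's similarity graph.

Any level of the hierarchy is embedded by t-SNE: the level's row-stochastic
transitions are symmetrised into joint probabilities P, and 2-D coordinates
are found by minimising KL(P || Q) where Q is the Student-t kernel over the
embedding.  The repulsive term is approximated with a Barnes-Hut quadtree at
opening angle ``theta`` (``theta = 0`` selects the exact O(n^2) computation
used as the oracle in tests).  Landmark weights deliberately do not enter the
objective - the area of influence determines display size and clustering
weight, not attraction - though a weighted attractive term is available for
experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .knn import TransitionMatrix
from ._barnes_hut import barnes_hut_repulsion

__all__ = [
    "JointProbabilities",
    "Embedding",
    "joint_probabilities",
    "tsne_embed",
    "exact_gradient",
    "kl_divergence",
]

_EPS = 1e-12


@dataclass
class JointProbabilities:
    """Symmetric joint probability matrix P with zero diagonal, summing to 1."""

    p: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.p.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        if abs(self.p.sum() - 1.0) > atol:
            raise AssertionError("P must sum to 1")
        asym = abs(self.p - self.p.T)
        if asym.nnz and asym.max() > 1e-12:
            raise AssertionError("P must be symmetric")
        if np.abs(self.p.diagonal()).max(initial=0.0) > 0:
            raise AssertionError("P must have zero diagonal")


@dataclass
class Embedding:
    """2-D coordinates for the nodes of one level, with the KL trace."""

    coords: np.ndarray  # (n, 2)
    node_ids: np.ndarray
    level_index: int = 0
    kl_trace: list[float] = field(default_factory=list)


def joint_probabilities(t: TransitionMatrix) -> JointProbabilities:
    """Symmetrise row-stochastic transitions: ``P = (T + T') / (2n)``,
    renormalised to sum to one with a zero diagonal."""
    p = (t.probs + t.probs.T) * (1.0 / (2.0 * t.n))
    p = sp.csr_matrix(p)
    p.setdiag(0)
    p.eliminate_zeros()
    total = p.sum()
    if total <= 0:
        raise ValueError("transition matrix has no off-diagonal mass")
    p = p * (1.0 / total)
    jp = JointProbabilities(p=sp.csr_matrix(p))
    jp.validate()
    return jp


def _student_t_dense(coords: np.ndarray) -> tuple[np.ndarray, float]:
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    w = 1.0 / (1.0 + d2 + _EPS)
    np.fill_diagonal(w, 0.0)
    return w, float(w.sum())


def exact_gradient(p: JointProbabilities, coords: np.ndarray) -> np.ndarray:
    """Dense O(n^2) t-SNE gradient ``4 sum_j (p_ij - q_ij) w_ij (y_i - y_j)``
    with ``w_ij = 1 / (1 + d_ij^2)`` and ``q = w / Z`` (test oracle)."""
    coords = np.asarray(coords, dtype=np.float64)
    w, z = _student_t_dense(coords)
    pd = np.asarray(p.p.todense())
    coef = (pd - w / z) * w
    grad = 4.0 * (coef.sum(axis=1)[:, None] * coords - coef @ coords)
    return grad


def kl_divergence(p: JointProbabilities, coords: np.ndarray) -> float:
    """Exact ``KL(P || Q)`` with the Student-t output kernel (dense)."""
    coords = np.asarray(coords, dtype=np.float64)
    w, z = _student_t_dense(coords)
    coo = p.p.tocoo()
    q = w[coo.row, coo.col] / z
    pp = coo.data
    return float(np.sum(pp * np.log(np.maximum(pp, _EPS) / np.maximum(q, _EPS))))


def _attractive(p_coo: sp.coo_matrix, coords: np.ndarray) -> np.ndarray:
    """``F_i = sum_j p_ij w_ij (y_i - y_j)`` over the sparse support of P."""
    row, col = p_coo.row, p_coo.col
    diff = coords[row] - coords[col]
    w = 1.0 / (1.0 + np.einsum("ij,ij->i", diff, diff))
    c = p_coo.data * w
    n = coords.shape[0]
    fx = np.bincount(row, weights=c * diff[:, 0], minlength=n)
    fy = np.bincount(row, weights=c * diff[:, 1], minlength=n)
    return np.stack([fx, fy], axis=1)


def _kl_sparse(p_coo: sp.coo_matrix, coords: np.ndarray, z: float) -> float:
    """KL over the support of P given the (possibly BH-approximated) Z."""
    diff = coords[p_coo.row] - coords[p_coo.col]
    w = 1.0 / (1.0 + np.einsum("ij,ij->i", diff, diff))
    pp = p_coo.data
    return float(np.sum(pp * (np.log(np.maximum(pp, _EPS)) - np.log(np.maximum(w / z, _EPS)))))


def _init_coords(node_ids: np.ndarray, seed: int, sigma: float = 1e-4) -> np.ndarray:
    """Per-node deterministic Gaussian init: each node's draw depends only on
    (seed, node id), so permuting the input permutes the rows identically."""
    ids = np.asarray(node_ids, dtype=np.uint64)

    def _mix(x: np.ndarray) -> np.ndarray:
        x = (x + np.uint64(0x9E3779B97F4A7C15)) * np.uint64(0xBF58476D1CE4E5B9)
        x ^= x >> np.uint64(27)
        x *= np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
        return x

    with np.errstate(over="ignore"):
        base = _mix(ids ^ (np.uint64(seed) * np.uint64(0xD1342543DE82EF95)))
        u1 = ((_mix(base + np.uint64(1)) >> np.uint64(11)) + np.uint64(1)).astype(np.float64) * 2.0**-53
        u2 = (_mix(base + np.uint64(2)) >> np.uint64(11)).astype(np.float64) * 2.0**-53
    r = np.sqrt(-2.0 * np.log(u1))
    return sigma * np.stack([r * np.cos(2 * np.pi * u2), r * np.sin(2 * np.pi * u2)], axis=1)


def tsne_embed(
    p: JointProbabilities,
    n_iter: int = 1000,
    theta: float = 0.5,
    learning_rate: float | None = None,
    early_exaggeration: float = 12.0,
    exaggeration_iter: int = 250,
    seed: int = 0,
    node_ids: np.ndarray | None = None,
    level_index: int = 0,
    trace_every: int = 50,
) -> Embedding:
    """Minimise KL(P || Q) by gradient descent with momentum and gains.

    Defaults follow the BH-SNE lineage: 1,000 iterations, x12 early
    exaggeration for 250 iterations, learning rate ``max(200, n / 12)``,
    momentum 0.5 switching to 0.8 after the exaggeration phase.  The KL
    divergence is recorded every ``trace_every`` iterations (exactly for
    small n, with the Barnes-Hut partition sum otherwise).
    """
    n = p.n
    if n < 2:
        raise ValueError("need at least 2 nodes to embed")
    if node_ids is None:
        node_ids = np.arange(n)
    node_ids = np.asarray(node_ids)
    if learning_rate is None:
        learning_rate = max(200.0, n / 12.0)

    coords = _init_coords(node_ids, seed)
    p_plain = sp.coo_matrix(p.p)
    p_ex = sp.coo_matrix(p.p * early_exaggeration)
    update = np.zeros_like(coords)
    gains = np.ones_like(coords)
    kl_trace: list[float] = []
    exact_kl = n <= 2000

    for it in range(n_iter):
        cur_p = p_ex if it < exaggeration_iter else p_plain
        momentum = 0.5 if it < exaggeration_iter else 0.8
        attr = _attractive(cur_p, coords)
        if theta > 0:
            rep, z = barnes_hut_repulsion(coords, theta)
        else:
            w, z = _student_t_dense(coords)
            coef = w * w
            rep = coef.sum(axis=1)[:, None] * coords - coef @ coords
        grad = 4.0 * (attr - rep / max(z, _EPS))
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite t-SNE gradient at iteration {it}")

        flip = np.sign(grad) != np.sign(update)
        gains = np.where(flip, gains + 0.2, gains * 0.8)
        np.clip(gains, 0.01, None, out=gains)
        update = momentum * update - learning_rate * gains * grad
        coords = coords + update
        coords -= coords.mean(axis=0)

        if (it + 1) % trace_every == 0 or it == n_iter - 1:
            if exact_kl:
                kl_trace.append(kl_divergence(p, coords))
            else:
                if theta <= 0:
                    zq = z
                else:
                    _, zq = barnes_hut_repulsion(coords, theta)
                kl_trace.append(_kl_sparse(p_plain, coords, zq))

    return Embedding(coords=coords, node_ids=node_ids, level_index=level_index, kl_trace=kl_trace)
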