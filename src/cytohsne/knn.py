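"""Weighted k-nearest-neighbour graph and its row-stochastic Markov chain.

The data level of the hierarchy is a kNN graph under Euclidean distance over
the full (transformed) marker expression.  Edge weights follow the SNE
convention: per-point Gaussian conditional probabilities whose bandwidth is
calibrated by bisection so that every row's Shannon entropy equals
``log2(perplexity)``.  The resulting row-stochastic matrix is the finite
Markov chain that all landmark-selection and influence random walks traverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix

__all__ = ["KnnGraph", "TransitionMatrix", "build_knn", "transition_from_knn"]

_LN2 = np.log(2.0)


@dataclass
class KnnGraph:
    """Exact or approximate Euclidean kNN graph over the rows of a matrix."""

    n_nodes: int
    neighbor_ids: np.ndarray  # (n_nodes, k) int64
    distances: np.ndarray  # (n_nodes, k) float64, sorted non-decreasing per row
    k: int
    exact: bool

    def validate(self) -> None:
        if np.any(self.neighbor_ids == np.arange(self.n_nodes)[:, None]):
            raise AssertionError("self-neighbours present")
        if np.any(np.diff(self.distances, axis=1) < 0):
            raise AssertionError("per-row distances not sorted")
        if self.neighbor_ids.min() < 0 or self.neighbor_ids.max() >= self.n_nodes:
            raise AssertionError("neighbour id out of range")


@dataclass
class TransitionMatrix:
    """Sparse row-stochastic similarity graph over the nodes of one level."""

    probs: sp.csr_matrix
    n: int

    def validate(self, atol: float = 1e-9) -> None:
        sums = np.asarray(self.probs.sum(axis=1)).ravel()
        if not np.allclose(sums, 1.0, atol=atol, rtol=0):
            worst = float(np.abs(sums - 1.0).max())
            raise AssertionError(f"rows not stochastic (max |sum-1| = {worst:.3g})")


def _exact_knn(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force Euclidean kNN with ties broken by lower node index."""
    n = x.shape[0]
    sq = np.einsum("ij,ij->i", x, x)
    ids = np.empty((n, k), dtype=np.int64)
    dst = np.empty((n, k), dtype=np.float64)
    chunk = max(1, min(n, int(2e7 // max(n, 1)) or 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (x[start:stop] @ x.T)
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        pd = np.take_along_axis(d2, part, axis=1)
        # sort by (distance, node id) for reproducible tie-breaks
        order = np.lexsort((part, pd), axis=1)
        ids[start:stop] = np.take_along_axis(part, order, axis=1)
        dst[start:stop] = np.sqrt(np.take_along_axis(pd, order, axis=1))
    return ids, dst


def _approx_knn(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Fast tree-based backend (scikit-learn).

    Pluggable stand-in for an approximate-NN index; the recall contract
    (>= 0.9 against brute force) holds trivially because tree search is exact,
    but unlike the brute-force oracle its tie-breaking is library-defined, so
    numeric tests use ``exact=True``.
    """
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dst, ids = nn.kneighbors(x)
    n = x.shape[0]
    out_ids = np.empty((n, k), dtype=np.int64)
    out_dst = np.empty((n, k), dtype=np.float64)
    rows = np.arange(n)
    for i in range(n):
        mask = ids[i] != rows[i]
        take = np.flatnonzero(mask)[:k]
        if take.size < k:  # self not among the k+1 (all-duplicate corner)
            take = np.arange(k + 1)[ids[i][: k + 1] != i][:k]
        out_ids[i] = ids[i][take]
        out_dst[i] = dst[i][take]
    return out_ids, out_dst


def build_knn(m: ExpressionMatrix | np.ndarray, k: int, exact: bool = True, seed: int = 0) -> KnnGraph:
    """Build the Euclidean kNN graph on the rows of ``m``.

    ``exact=True`` is the deterministic brute-force reference used by all
    numeric tests; ``exact=False`` selects the fast backend.  ``seed`` is
    accepted for interface stability (the installed backends are
    deterministic and ignore it).
    """
    if isinstance(m, ExpressionMatrix):
        if not m.transformed:
            warnings.warn("building kNN on untransformed expression values", stacklevel=2)
        x = m.values
    else:
        x = np.asarray(m, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to build a kNN graph")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    ids, dst = (_exact_knn if exact else _approx_knn)(x, k)
    return KnnGraph(n_nodes=n, neighbor_ids=ids, distances=dst, k=k, exact=exact)


def _calibrate_rows(d2: np.ndarray, perplexity: float, tol: float = 1e-5, max_iter: int = 200) -> np.ndarray:
    """Per-row Gaussian weights with entropy log2(perplexity), by bisection.

    ``d2`` holds squared neighbour distances, one row per point.  Returns the
    unnormalised weight matrix ``exp(-beta_i * d2)`` with each row's Shannon
    entropy (bits) within ``tol`` of the target.  Rows whose distances are all
    zero get uniform weights.
    """
    n, k = d2.shape
    target = np.log2(perplexity)
    d2 = d2 - d2[:, :1]  # shift by the smallest squared distance for stability
    beta = np.ones(n)
    lo = np.zeros(n)
    hi = np.full(n, np.inf)
    w = np.empty_like(d2)
    degenerate = d2.max(axis=1) <= 0
    for _ in range(max_iter):
        np.exp(-beta[:, None] * d2, out=w)
        sw = w.sum(axis=1)
        h = (np.log(sw) + beta * np.einsum("ij,ij->i", d2, w) / sw) / _LN2
        diff = h - target
        done = (np.abs(diff) < tol) | degenerate
        if done.all():
            break
        too_flat = (diff > 0) & ~done  # entropy too high -> narrow the kernel
        lo[too_flat] = beta[too_flat]
        beta[too_flat] = np.where(np.isinf(hi[too_flat]), beta[too_flat] * 2.0, (beta[too_flat] + hi[too_flat]) / 2.0)
        too_sharp = (diff < 0) & ~done
        hi[too_sharp] = beta[too_sharp]
        beta[too_sharp] = np.where(lo[too_sharp] == 0, beta[too_sharp] / 2.0, (beta[too_sharp] + lo[too_sharp]) / 2.0)
    np.exp(-beta[:, None] * d2, out=w)
    if degenerate.any():
        w[degenerate] = 1.0
    return w


def transition_from_knn(g: KnnGraph, perplexity: float = 30.0) -> TransitionMatrix:
    """Convert a kNN graph into the row-stochastic transition matrix.

    Row ``i`` holds ``p(j|i) = exp(-d(i,j)^2 / (2 sigma_i^2))`` over the k
    neighbours of ``i``, with ``sigma_i`` calibrated so that the row entropy
    equals ``log2(perplexity)``; rows are normalised to sum to one.
    """
    if perplexity > g.k:
        raise ValueError(f"perplexity ({perplexity}) must not exceed k ({g.k})")
    if perplexity <= 1:
        raise ValueError("perplexity must be > 1")
    w = _calibrate_rows(g.distances**2, perplexity)
    w /= w.sum(axis=1, keepdims=True)
    n = g.n_nodes
    indptr = np.arange(0, n * g.k + 1, g.k)
    probs = sp.csr_matrix((w.ravel(), g.neighbor_ids.ravel(), indptr), shape=(n, n))
    probs.sort_indices()
    t = TransitionMatrix(probs=probs, n=n)
    t.validate()
    return t
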