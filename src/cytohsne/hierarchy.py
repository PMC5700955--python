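"""Multi-level landmark hierarchy built by random walks on a Markov chain.

The data-level kNN similarity graph is treated as a finite Markov chain.
Landmarks for the next coarser level are the best-connected nodes: from every
node a fixed number of fixed-length random walks is launched and nodes whose
endpoint hit count exceeds ``beta`` times the uniform expectation are kept.
A second set of walks, terminated at the first landmark reached, yields each
node's influence distribution over landmarks; the support of a landmark's
influence column is its area of influence (AoI).  Landmark similarity is the
influence-weighted AoI overlap, which conserves represented cell mass exactly
and replaces Euclidean re-computation (the source of manifold "shortcuts") at
every level above the data.

Counts per level and the stopping rule follow mass-cytometry practice: each
level shrinks roughly an order of magnitude, so ``log10(n_cells / 100)``
levels leave an overview of order 1,000 landmarks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .io import ExpressionMatrix
from .knn import TransitionMatrix, build_knn, transition_from_knn
from ._walks import endpoint_hits, influence_endpoints

__all__ = [
    "HsneParams",
    "InfluenceMatrix",
    "LevelGraph",
    "HsneHierarchy",
    "recommended_levels",
    "select_landmarks",
    "exact_hit_distribution",
    "compute_influence",
    "build_next_level",
    "build_hierarchy",
    "save_hierarchy",
    "load_hierarchy",
]

logger = logging.getLogger(__name__)


@dataclass
class HsneParams:
    """Construction parameters.

    Defaults are the standard hierarchy-construction settings for mass
    cytometry: 100 selection walks of length 15 per node and 15 influence
    walks per node.  ``beta`` scales the landmark threshold (a node is kept
    when its endpoint hits reach ``beta`` times the uniform expectation);
    ``k`` and ``perplexity`` shape the data-level similarity graph.
    """

    n_walks_selection: int = 100
    walk_length: int = 15
    n_walks_influence: int = 15
    beta: float = 1.5
    k: int = 100
    perplexity: float = 30.0
    n_levels: int = 2
    seed: int = 0
    max_influence_walk: int = 150
    exact_knn: bool = True

    def __post_init__(self) -> None:
        for name in ("n_walks_selection", "walk_length", "n_walks_influence", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels (data + one landmark level)")
        if self.max_influence_walk < self.walk_length:
            raise ValueError("max_influence_walk must be >= walk_length")


@dataclass
class InfluenceMatrix:
    """Sparse (parent-node x landmark) matrix of walk-termination fractions.

    Row ``i`` is node ``i``'s influence distribution over landmarks (sums to
    one); the support of column ``j`` is the AoI of landmark ``j``.
    """

    influence: sp.csr_matrix
    landmarks: np.ndarray  # parent-level node id per column

    def validate(self, atol: float = 1e-9) -> None:
        sums = np.asarray(self.influence.sum(axis=1)).ravel()
        if not np.allclose(sums, 1.0, atol=atol, rtol=0):
            raise AssertionError("influence rows must sum to 1")
        if self.influence.nnz and (self.influence.data.min() < 0 or self.influence.data.max() > 1 + atol):
            raise AssertionError("influence entries must lie in [0, 1]")


@dataclass
class LevelGraph:
    """One coarse hierarchy level: landmarks, weights and their similarity graph."""

    landmark_parent_ids: np.ndarray  # index of each landmark in the preceding level
    weights: np.ndarray  # data-level cells represented per landmark
    similarities: sp.csr_matrix  # symmetric, zero diagonal
    transition: TransitionMatrix
    level_index: int

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_parent_ids)

    def validate(self, n_cells: int | None = None) -> None:
        if len(np.unique(self.landmark_parent_ids)) != self.n_landmarks:
            raise AssertionError("landmark parent ids must be unique")
        asym = abs(self.similarities - self.similarities.T)
        if asym.nnz and asym.max() > 1e-9 * max(1.0, self.similarities.max()):
            raise AssertionError("similarities must be symmetric")
        if np.abs(self.similarities.diagonal()).max(initial=0.0) > 0:
            raise AssertionError("similarities must have zero diagonal")
        if n_cells is not None and not np.isclose(self.weights.sum(), n_cells, rtol=1e-6):
            raise AssertionError("landmark weights must conserve the data-level cell count")
        self.transition.validate()


@dataclass
class HsneHierarchy:
    """Ordered levels from the data level (0) to the coarsest overview.

    ``level_graphs[s - 1]`` and ``influences[s - 1]`` describe level ``s`` for
    ``s >= 1``; ``influences[s - 1]`` maps level ``s - 1`` nodes to level
    ``s`` landmarks.
    """

    params: HsneParams
    n_cells: int
    data_transition: TransitionMatrix
    level_graphs: list[LevelGraph] = field(default_factory=list)
    influences: list[InfluenceMatrix] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return 1 + len(self.level_graphs)

    @property
    def level_sizes(self) -> list[int]:
        return [self.n_cells] + [lg.n_landmarks for lg in self.level_graphs]

    def transition_at(self, level: int) -> TransitionMatrix:
        if level == 0:
            return self.data_transition
        return self.level_graphs[level - 1].transition

    def similarities_at(self, level: int) -> sp.csr_matrix:
        """Symmetric similarity graph of a level (symmetrised transition at level 0)."""
        if level == 0:
            p = self.data_transition.probs
            s = (p + p.T) * 0.5
            s.setdiag(0)
            s.eliminate_zeros()
            return s.tocsr()
        return self.level_graphs[level - 1].similarities

    def weights_at(self, level: int) -> np.ndarray:
        if level == 0:
            return np.ones(self.n_cells)
        return self.level_graphs[level - 1].weights


def recommended_levels(n_cells: int) -> int:
    """Recommended number of hierarchy levels, ``log10(n_cells / 100)``.

    Rounded to the nearest integer, never fewer than 2; every level shrinks
    the landmark count by roughly one order of magnitude, so this leaves an
    overview level of order 1,000 landmarks.
    """
    if n_cells <= 100:
        raise ValueError("level rule needs more than 100 cells")
    return max(2, int(np.floor(np.log10(n_cells / 100.0) + 0.5)))


def _row_cumsum(m: sp.csr_matrix) -> np.ndarray:
    cs = np.cumsum(m.data)
    ends = m.indptr[1:-1]
    prev = np.where(ends > 0, cs[ends - 1], 0.0)
    offsets = np.repeat(np.concatenate(([0.0], prev)), np.diff(m.indptr))
    return cs - offsets


def _force_component_landmarks(probs: sp.csr_matrix, selected: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Guarantee at least one landmark in every terminal strongly connected
    component (hence in every weakly connected component), so that
    landmark-absorbed walks terminate almost surely."""
    n_comp, comp = connected_components(probs, directed=True, connection="strong")
    coo = probs.tocoo()
    nonterminal = np.zeros(n_comp, dtype=bool)
    cross = comp[coo.row] != comp[coo.col]
    nonterminal[np.unique(comp[coo.row[cross]])] = True  # has outgoing edges
    has_landmark = np.zeros(n_comp, dtype=bool)
    has_landmark[comp[selected]] = True
    mask = np.zeros(probs.shape[0], dtype=bool)
    mask[selected] = True
    for c in range(n_comp):
        if nonterminal[c] or has_landmark[c]:
            continue
        members = np.flatnonzero(comp == c)
        mask[members[np.argmax(hits[members])]] = True  # argmax ties -> lowest id
    return np.flatnonzero(mask)


def select_landmarks(t: TransitionMatrix, params: HsneParams, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Select landmark nodes by Monte-Carlo endpoint counting.

    From every node, ``n_walks_selection`` walks of exactly ``walk_length``
    steps are simulated; node ``i`` becomes a landmark iff its endpoint hit
    count reaches ``beta * n_walks_selection`` (the uniform expectation times
    ``beta``).  Every terminal strongly connected component is forced to
    contain at least its maximum-hit node, so influence walks can always
    terminate.  Returns ``(sorted landmark ids, hit counts for all nodes)``.
    """
    if t.n == 0 or t.probs.nnz == 0:
        raise ValueError("empty transition matrix")
    if seed is None:
        seed = params.seed
    cum = _row_cumsum(t.probs)
    hits = endpoint_hits(t.probs.indptr, t.probs.indices, cum, params.walk_length, params.n_walks_selection, seed)
    threshold = params.beta * params.n_walks_selection
    selected = np.flatnonzero(hits >= threshold)
    selected = _force_component_landmarks(t.probs, selected, hits)
    return selected, hits


def exact_hit_distribution(t: TransitionMatrix, walk_length: int) -> np.ndarray:
    """Exact endpoint distribution of length-``walk_length`` walks under a
    uniform start: the vector ``(1/n) 1^T T^L`` (test oracle for
    :func:`select_landmarks`)."""
    v = np.full(t.n, 1.0 / t.n)
    for _ in range(walk_length):
        v = t.probs.T @ v
    return v


def compute_influence(
    t: TransitionMatrix,
    landmarks: np.ndarray,
    params: HsneParams,
    seed: int | None = None,
) -> InfluenceMatrix:
    """Walk from every node until a landmark absorbs the walk.

    Entry ``(i, l)`` is the fraction of node ``i``'s ``n_walks_influence``
    walks that terminated at landmark ``l``; a walk started at a landmark
    terminates immediately at itself.  Walks exceeding
    ``max_influence_walk`` steps restart (counted and logged); a node whose
    walks all fail after 10 restarts raises.
    """
    landmarks = np.asarray(landmarks, dtype=np.int64)
    if landmarks.size == 0:
        raise ValueError("need at least one landmark")
    if seed is None:
        seed = params.seed
    landmark_col = np.full(t.n, -1, dtype=np.int64)
    landmark_col[landmarks] = np.arange(landmarks.size)
    cum = _row_cumsum(t.probs)
    endpoints, restarts = influence_endpoints(
        t.probs.indptr,
        t.probs.indices,
        cum,
        landmark_col,
        params.n_walks_influence,
        params.max_influence_walk,
        10,
        np.uint64(seed) + np.uint64(0x9E37),  # decorrelate from selection walks
    )
    if restarts:
        logger.info("influence walks restarted %d times (cap %d steps)", restarts, params.max_influence_walk)
    failed = endpoints < 0
    if failed.any():
        bad_nodes = np.flatnonzero(failed.all(axis=1))
        if bad_nodes.size:
            raise RuntimeError(f"influence walks from node {int(bad_nodes[0])} failed to reach any landmark after 10 restarts")
        logger.warning("%d influence walks failed and were dropped", int(failed.sum()))
    n_ok = (~failed).sum(axis=1).astype(np.float64)
    rows = np.repeat(np.arange(t.n), params.n_walks_influence)[~failed.ravel()]
    cols = endpoints.ravel()[~failed.ravel()]
    counts = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(t.n, landmarks.size)).tocsr()
    counts.sum_duplicates()
    infl = sp.csr_matrix(counts.multiply(1.0 / n_ok[:, None]))
    out = InfluenceMatrix(influence=infl, landmarks=landmarks)
    out.validate()
    return out


def build_next_level(
    influence: InfluenceMatrix,
    parent_weights: np.ndarray,
    level_index: int = 1,
    overlap: str = "influence",
) -> LevelGraph:
    """Derive the coarser-level similarity graph from AoI overlap.

    ``overlap="influence"`` (default) weights the overlap by the influence
    fractions, ``s(l, m) = sum_i w_i I(i, l) I(i, m)`` for ``l != m``, which
    makes cell-mass conservation exact.  ``overlap="count"`` counts parent
    weight in the plain AoI intersection, ``sum_i w_i [I(i,l)>0][I(i,m)>0]``
    (literal "number of data points in the overlapping area").
    Landmark weights are ``w(l) = sum_i w_i I(i, l)`` in both modes.
    """
    parent_weights = np.asarray(parent_weights, dtype=np.float64)
    infl = influence.influence
    weights = infl.T @ parent_weights
    if np.any(weights <= 0):
        raise AssertionError("landmark with zero weight (influence(l,l)=1 should prevent this)")
    if overlap == "influence":
        base = infl
    elif overlap == "count":
        base = infl.copy()
        base.data = np.ones_like(base.data)
    else:
        raise ValueError(f"unknown overlap mode {overlap!r}")
    weighted = base.multiply(parent_weights[:, None]).tocsc()
    sim = (base.T @ weighted).tocsr()
    sim.setdiag(0)
    sim.eliminate_zeros()
    sim = ((sim + sim.T) * 0.5).tocsr()  # numerically enforce symmetry

    row_sums = np.asarray(sim.sum(axis=1)).ravel()
    isolated = np.flatnonzero(row_sums == 0)
    trans = sim.copy().tolil() if isolated.size else sim.copy()
    if isolated.size:
        logger.warning("%d isolated landmarks get self-loop transitions", isolated.size)
        for i in isolated:
            trans[i, i] = 1.0
        trans = trans.tocsr()
        row_sums = np.asarray(trans.sum(axis=1)).ravel()
    trans = sp.csr_matrix(trans.multiply(1.0 / row_sums[:, None]))
    transition = TransitionMatrix(probs=trans, n=sim.shape[0])
    transition.validate()
    return LevelGraph(
        landmark_parent_ids=influence.landmarks.copy(),
        weights=weights,
        similarities=sim,
        transition=transition,
        level_index=level_index,
    )


def _level_seed(seed: int, level: int) -> int:
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(level,)).generate_state(1)[0])


def _droppable_landmarks(probs: sp.csr_matrix, landmarks: np.ndarray, isolated: np.ndarray) -> np.ndarray:
    """Isolated landmarks that are safe to remove.

    A landmark may be dropped unless it is the only landmark of a terminal
    strongly connected component (removing it would leave walks from that
    component with nowhere to terminate).
    """
    n_comp, comp = connected_components(probs, directed=True, connection="strong")
    coo = probs.tocoo()
    nonterminal = np.zeros(n_comp, dtype=bool)
    cross = comp[coo.row] != comp[coo.col]
    nonterminal[np.unique(comp[coo.row[cross]])] = True
    counts = np.bincount(comp[landmarks], minlength=n_comp)
    drop = []
    for l in landmarks[isolated]:
        c = comp[l]
        if nonterminal[c] or counts[c] > 1:
            counts[c] -= 1
            drop.append(l)
    return np.asarray(drop, dtype=np.int64)


def build_hierarchy(m: ExpressionMatrix | np.ndarray, params: HsneParams) -> HsneHierarchy:
    """Assemble the full hierarchy: kNN chain at level 0, then iterated
    landmark selection, influence computation and AoI-overlap coarsening."""
    x = m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=np.float64)
    n_cells = x.shape[0]
    if n_cells <= params.k:
        raise ValueError("need more cells than k")
    logger.info("level 0: kNN graph (n=%d, k=%d, exact=%s)", n_cells, params.k, params.exact_knn)
    g = build_knn(m, params.k, exact=params.exact_knn, seed=params.seed)
    t = transition_from_knn(g, params.perplexity)
    h = HsneHierarchy(params=params, n_cells=n_cells, data_transition=t)
    weights = np.ones(n_cells)
    for s in range(1, params.n_levels):
        seed_s = _level_seed(params.seed, s)
        landmarks, hits = select_landmarks(t, params, seed=seed_s)
        if landmarks.size >= t.n:
            raise RuntimeError(
                f"level {s} did not shrink ({landmarks.size} landmarks from {t.n} nodes); use fewer levels"
            )
        if landmarks.size < 10 and s < params.n_levels - 1:
            raise RuntimeError(
                f"level {s} collapsed to {landmarks.size} landmarks before the final level; use fewer levels"
            )
        # an isolated landmark (AoI overlapping no other landmark's) is a
        # degenerate artifact, usually an outlier cell absorbing only its own
        # walks; prune such landmarks where termination allows and let their
        # nodes walk to real neighbourhoods instead
        for _ in range(4):
            infl = compute_influence(t, landmarks, params, seed=seed_s)
            lg = build_next_level(infl, weights, level_index=s)
            deg = np.asarray((lg.similarities > 0).sum(axis=1)).ravel()
            isolated = deg == 0
            if not isolated.any():
                break
            drop = _droppable_landmarks(t.probs, landmarks, isolated)
            if drop.size == 0:
                break
            logger.info("level %d: pruning %d isolated landmarks", s, drop.size)
            landmarks = np.setdiff1d(landmarks, drop)
        lg.validate(n_cells=n_cells)
        logger.info("level %d: %d landmarks (shrinkage %.1fx)", s, lg.n_landmarks, t.n / lg.n_landmarks)
        h.level_graphs.append(lg)
        h.influences.append(infl)
        t = lg.transition
        weights = lg.weights
    return h


# ---------------------------------------------------------------------------
# persistence: directory container of MTX matrices + CSV tables + manifest


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def save_hierarchy(h: HsneHierarchy, outdir: str | os.PathLike) -> str:
    """Persist a hierarchy as a directory of MatrixMarket + CSV files with a
    JSON manifest (params, level sizes, checksums)."""
    from scipy.io import mmwrite
    import pandas as pd

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    files: dict[str, str] = {}

    def _write_mtx(name: str, mat: sp.spmatrix) -> None:
        path = os.path.join(outdir, name)
        mmwrite(path, sp.coo_matrix(mat), precision=17)
        files[name] = _sha256(path)

    _write_mtx("level0_transition.mtx", h.data_transition.probs)
    for s, (lg, infl) in enumerate(zip(h.level_graphs, h.influences), start=1):
        _write_mtx(f"level{s}_similarities.mtx", lg.similarities)
        _write_mtx(f"level{s}_influence.mtx", infl.influence)
        table = pd.DataFrame({"landmark_parent_id": lg.landmark_parent_ids, "weight": lg.weights})
        path = os.path.join(outdir, f"level{s}_landmarks.csv")
        table.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
        files[f"level{s}_landmarks.csv"] = _sha256(path)

    manifest = {
        "format": "cytohsne-hierarchy-v1",
        "params": asdict(h.params),
        "n_cells": h.n_cells,
        "level_sizes": h.level_sizes,
        "files": files,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def load_hierarchy(indir: str | os.PathLike) -> HsneHierarchy:
    from scipy.io import mmread
    import pandas as pd

    indir = os.fspath(indir)
    with open(os.path.join(indir, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "cytohsne-hierarchy-v1":
        raise ValueError("not a cytohsne hierarchy container")
    params = HsneParams(**manifest["params"])
    n_cells = int(manifest["n_cells"])
    t0 = sp.csr_matrix(mmread(os.path.join(indir, "level0_transition.mtx")))
    h = HsneHierarchy(params=params, n_cells=n_cells, data_transition=TransitionMatrix(probs=t0, n=n_cells))
    n_levels = len(manifest["level_sizes"])
    for s in range(1, n_levels):
        sim = sp.csr_matrix(mmread(os.path.join(indir, f"level{s}_similarities.mtx")))
        infl = sp.csr_matrix(mmread(os.path.join(indir, f"level{s}_influence.mtx")))
        table = pd.read_csv(os.path.join(indir, f"level{s}_landmarks.csv"))
        row_sums = np.asarray(sim.sum(axis=1)).ravel()
        trans = sim.tolil(copy=True)
        for i in np.flatnonzero(row_sums == 0):
            trans[i, i] = 1.0
            row_sums[i] = 1.0
        trans = sp.csr_matrix(sp.csr_matrix(trans).multiply(1.0 / row_sums[:, None]))
        lg = LevelGraph(
            landmark_parent_ids=table["landmark_parent_id"].to_numpy(),
            weights=table["weight"].to_numpy(),
            similarities=sim,
            transition=TransitionMatrix(probs=trans, n=sim.shape[0]),
            level_index=s,
        )
        h.level_graphs.append(lg)
        h.influences.append(InfluenceMatrix(influence=infl, landmarks=lg.landmark_parent_ids))
    return h
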