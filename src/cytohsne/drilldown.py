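"""Exploration semantics: expand landmark selections through AoIs, re-embed,
and trace any selection down to data-level cell identifiers.

A selection at level ``s`` expands to the preceding level by keeping every
node whose total influence on the selected landmarks reaches a threshold
(0 gives the exact union of the AoIs; the default 0.5 guarantees a node joins
at most one of two disjoint selections).  Quantitative tracing to single
cells instead assigns every node to its maximum-influence landmark (ties to
the lower landmark id): AoIs overlap, but the argmax chain partitions the
data, so disjoint landmark selections count every cell exactly once - the
mechanism that makes downsampling unnecessary.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .embedding import Embedding, joint_probabilities, tsne_embed
from .hierarchy import HsneHierarchy
from .knn import TransitionMatrix

__all__ = ["Selection", "expand_selection", "embed_selection", "trace_to_data", "save_selection", "load_selection"]


@dataclass
class Selection:
    """A set of node indices at one hierarchy level."""

    level_index: int
    node_ids: np.ndarray
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.node_ids = np.unique(np.asarray(self.node_ids, dtype=np.int64))

    def validate(self, h: HsneHierarchy) -> None:
        if not 0 <= self.level_index < h.n_levels:
            raise ValueError(f"level {self.level_index} outside hierarchy")
        n = h.level_sizes[self.level_index]
        if self.node_ids.size and (self.node_ids.min() < 0 or self.node_ids.max() >= n):
            raise ValueError("selection contains node ids outside the level")


def expand_selection(h: HsneHierarchy, s: Selection, influence_threshold: float = 0.5) -> Selection:
    """Expand a landmark selection to the preceding level through the AoIs.

    Keeps parent-level nodes whose summed influence on the selected landmarks
    is at least ``influence_threshold``; with threshold 0 this is exactly the
    union of the selected landmarks' AoIs.
    """
    if s.level_index < 1:
        raise ValueError("cannot expand below the data level")
    s.validate(h)
    infl = h.influences[s.level_index - 1].influence
    total = np.asarray(infl[:, s.node_ids].sum(axis=1)).ravel()
    if influence_threshold <= 0:
        keep = np.flatnonzero(total > 0)
    else:
        keep = np.flatnonzero(total >= influence_threshold)
    if keep.size == 0:
        raise ValueError("expansion is empty; lower the influence threshold")
    return Selection(level_index=s.level_index - 1, node_ids=keep, provenance=f"expand({s.provenance})")


def embed_selection(h: HsneHierarchy, s: Selection, **embed_params) -> Embedding:
    """Re-embed only the selected nodes of a level.

    The level's similarity graph is restricted to the selection, transitions
    are re-normalised over the restricted support, and the result is embedded
    like a full level.  A node with no internal edges keeps a self-loop (it
    contributes no attraction); a selection with no internal edges at all
    cannot be embedded coherently and raises.
    """
    s.validate(h)
    ids = s.node_ids
    if ids.size < 2:
        raise ValueError("need at least 2 selected nodes to embed")
    sim = h.similarities_at(s.level_index)
    sub = sp.csr_matrix(sim[ids][:, ids])
    if sub.nnz == 0:
        raise ValueError("selection has no internal similarity edges; nothing to embed coherently")
    row_sums = np.asarray(sub.sum(axis=1)).ravel()
    isolated = np.flatnonzero(row_sums == 0)
    if isolated.size:
        sub = sub.tolil()
        for i in isolated:
            sub[i, i] = 1.0
        sub = sub.tocsr()
        row_sums[isolated] = 1.0
    trans = sp.csr_matrix(sub.multiply(1.0 / row_sums[:, None]))
    t = TransitionMatrix(probs=trans, n=ids.size)
    t.validate()
    p = joint_probabilities(t)
    embed_params.setdefault("level_index", s.level_index)
    return tsne_embed(p, node_ids=ids, **embed_params)


def _argmax_owner(infl: sp.csr_matrix) -> np.ndarray:
    """Per-row argmax column of a CSR matrix, ties to the lower column id."""
    n = infl.shape[0]
    owner = np.full(n, -1, dtype=np.int64)
    indptr, indices, data = infl.indptr, infl.indices, infl.data
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        if lo == hi:
            continue
        seg = data[lo:hi]
        best = lo + int(np.argmax(seg))
        # np.argmax returns the first maximum; CSR indices are sorted
        # ascending, so this is already the lowest landmark id.
        owner[i] = indices[best]
    return owner


def trace_to_data(h: HsneHierarchy, s: Selection) -> np.ndarray:
    """Trace a selection down to data-level cell indices (argmax-influence).

    Every node at each level is owned by its maximum-influence landmark; the
    traced set is all cells whose ownership chain ends in the selection.  For
    a partition of a level into disjoint selections this assigns every cell
    to exactly one selection.
    """
    s.validate(h)
    members = np.zeros(h.level_sizes[s.level_index], dtype=bool)
    members[s.node_ids] = True
    for level in range(s.level_index, 0, -1):
        owner = _argmax_owner(h.influences[level - 1].influence)
        members = members[owner] & (owner >= 0)
    return np.flatnonzero(members)


def save_selection(s: Selection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"level_index": int(s.level_index), "node_ids": [int(i) for i in s.node_ids], "provenance": s.provenance},
            fh,
        )
        fh.write("\n")


def load_selection(path: str | os.PathLike) -> Selection:
    with open(path) as fh:
        d = json.load(fh)
    return Selection(level_index=d["level_index"], node_ids=np.asarray(d["node_ids"]), provenance=d.get("provenance", "manual"))
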