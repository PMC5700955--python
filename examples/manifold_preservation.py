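"""Show that AoI-overlap similarities avoid Euclidean 'shortcuts'.

Two curved sheets lie close in 3-D Euclidean space but far apart along the
manifold.  At full sampling density the kNN graph stays on-sheet, and the
hierarchy's area-of-influence similarities keep the sheets apart at the
landmark level.  Rebuilding a Euclidean kNN graph on the landmark positions
instead - equivalent to downsampling and re-linking - sends a substantial
share of similarity mass across the gap: the shortcut the hierarchy exists
to avoid.
"""

import numpy as np
import scipy.sparse as sp

import cytohsne as ch
from cytohsne.knn import build_knn, transition_from_knn


def cross_mass(sim, labels):
    coo = sp.coo_matrix(sim)
    return coo.data[labels[coo.row] != labels[coo.col]].sum() / coo.data.sum()


data = ch.make_manifold3d(n_cells=10_000, seed=5)
h = ch.build_hierarchy(data.matrix, ch.HsneParams(k=15, perplexity=8.0, n_levels=2, seed=5))
lg = h.level_graphs[0]
lab = data.labels[lg.landmark_parent_ids]
print("landmarks:", lg.n_landmarks)
print(f"cross-sheet mass, AoI-overlap similarities: {100 * cross_mass(lg.similarities, lab):.3f}%")

pos = data.matrix.values[lg.landmark_parent_ids]
t = transition_from_knn(build_knn(pos, k=15), perplexity=8.0)
base = cross_mass((t.probs + t.probs.T) * 0.5, lab)
print(f"cross-sheet mass, Euclidean kNN on landmarks: {100 * base:.3f}%  (the shortcut baseline)")

# at overview density, Euclidean 1-NNs cross the gap - structure a random
# downsample would lose
sub = np.random.default_rng(5).choice(10_000, size=200, replace=False)
g = build_knn(data.matrix.values[sub], k=1)
frac = (data.labels[sub][g.neighbor_ids[:, 0]] != data.labels[sub]).mean()
print(f"downsampled to 200 points, {100 * frac:.1f}% of Euclidean 1-NNs cross the gap")
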