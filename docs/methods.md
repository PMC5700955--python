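# Methods

This note records the model, the numerical choices, and the decisions taken
where the design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The package operates on a cells × markers matrix of arcsinh-transformed
expression values (`asinh(x / c)`, cofactor `c = 5` by default, the standard
variance-stabilising transform for ion counts). Inputs are assumed
pre-gated: live, single-cell events only. Missing values are rejected rather
than imputed, because the Euclidean distance that defines the similarity
graph has no principled missing-data semantics.

The data manifold is assumed to be *locally* Euclidean: the kNN graph with
per-point Gaussian bandwidths is meaningful at the sampling density of the
data level. Everything above the data level deliberately avoids Euclidean
geometry — coarse similarities are areas-of-influence overlaps — because at
reduced (landmark) density Euclidean neighbourhoods jump between manifold
sheets ("shortcuts").

## Parameters

| Parameter | Default | Units / meaning |
| --- | --- | --- |
| `cofactor` | 5 | arcsinh divisor for raw counts |
| `k` | 100 | neighbours per cell in the data-level graph |
| `perplexity` | 30 | effective neighbour count for bandwidth calibration |
| `n_walks_selection` | 100 | fixed-length walks per node for landmark scoring |
| `walk_length` | 15 | steps per selection walk |
| `beta` | 1.5 | landmark threshold, × the uniform expected hit count |
| `n_walks_influence` | 15 | landmark-absorbed walks per node |
| `max_influence_walk` | 150 | step cap before an influence walk restarts |
| `n_levels` | `round(log10(n/100))`, min 2 | hierarchy depth incl. the data level |
| `theta` | 0.5 | Barnes–Hut opening angle (0 = exact) |
| `n_iter` | 1000 | embedding gradient-descent iterations |
| `kernel_fraction` | 0.05 | GMS bandwidth as a fraction of the embedding extent |
| `S` | 256 | density grid resolution |

The walk counts (100/15/15), the grid size `S = 256`, the cofactor, and the
level rule are the standard operating settings for mass cytometry. `k`,
`perplexity` and `beta` are not published for the reference workflow;
`k = 100` and `perplexity = 30` follow the BH-SNE lineage the embedding
adapts, and `beta = 1.5` gives the expected order-of-magnitude shrinkage per
level (measured ratios on 100k-cell mixtures: ≈5.5 and ≈18). All are
exposed in `HsneParams`.

The GMS kernel fraction is the primary tuning knob of the clustering, and
published analyses tune it per data set (0.18 in one case, chosen there to
match a reference cluster count). The default 0.05 suits well-separated
overview embeddings; increase it to merge fine structure.

## Landmark selection and influence

Selection scores are endpoint counts of fixed-length walks (not visit
counts along the walk): with `n` nodes each launching `N` walks, a node
becomes a landmark when its endpoint count reaches `beta × N`. Endpoint
counting matches the walk definition (walks "of predefined length") and
converges to the `L`-step hit distribution `(1/n)·1ᵀT^L`, against which the
Monte-Carlo frequencies are tested (r ≥ 0.95 at 1,000 walks/node).

Two refinements guarantee well-posedness:

* **Termination forcing.** Influence walks must always reach a landmark, so
  every *terminal* strongly connected component of the transition graph is
  forced to contain at least its maximum-hit node (ties to the lower node
  id). This also guarantees at least one landmark per weakly connected
  component. Influence walks additionally carry a step cap
  (`max_influence_walk`) with restart, bounding runtime on pathological
  graphs; a node whose walks all fail after 10 restarts raises an error.
* **Orphan pruning.** A landmark whose AoI overlaps no other landmark's
  (a zero row of the coarse similarity graph, typically an outlier cell
  that absorbs only its own walks) is pruned and influence is recomputed,
  unless it is the sole landmark of a terminal component. Orphans carry no
  similarity information; left in place they are flung to the embedding
  periphery by unopposed repulsion and destabilise the extent-scaled GMS
  bandwidth. Pruning preserves exact weight conservation.

## Coarse similarities

Landmark similarity defaults to influence-weighted overlap
`s(l, m) = Σ_i w_i I(i, l) I(i, m)` (`l ≠ m`), which is continuous in the
influence fractions and makes weight conservation exact
(`Σ_l w(l) = Σ_i w_i` because influence rows sum to one). A literal
"count" mode — parent weight summed over the plain AoI intersection,
ignoring influence magnitudes — is available via
`build_next_level(..., overlap="count")`. Transitions at coarse levels are
the row-normalised similarities; an isolated row (possible only for a
forced component landmark) receives a self-loop.

## Random-number discipline

Every walk stream is derived from the master seed and the starting node id
(splitmix64 key expansion feeding xorshift64*), so results are bit-identical
for a given seed regardless of execution order or parallelism. Per-level
seeds come from `numpy.random.SeedSequence(seed, spawn_key=(level,))`.
Embedding initialisation is an isotropic Gaussian (σ = 1e-4) hashed from
(seed, node id), which makes the embedding permutation-equivariant in the
input order. Exact-kNN mode is the deterministic reference path; the fast
backend (scikit-learn tree search) is also deterministic but its
tie-breaking is library-defined, so numeric tests use exact mode.

## Embedding

The optimiser is standard BH-SNE gradient descent: 1,000 iterations, early
exaggeration ×12 for 250 iterations, learning rate `max(200, n/12)`,
momentum 0.5 → 0.8 after exaggeration, per-parameter gains in [0.01, ∞).
The Barnes–Hut quadtree summarises a cell when `side/distance < theta`;
coincident points are merged into one leaf with integer mass, so degenerate
configurations terminate. `theta = 0` switches to the dense O(n²) gradient,
which doubles as the oracle in tests (BH at `theta = 0.5` agrees within 5%
on 500-point instances; the dense gradient agrees with finite differences
of the KL objective to 1e-4). Landmark weights do not enter the objective —
the AoI determines display size and clustering weight, not attraction — but
a weighted attractive term can be obtained by scaling P before embedding.

## Clustering

Gaussian mean shift runs point-wise on the continuous KDE (the S×S grid is
the display/density-feature artefact, not the ascent surface, because
grid-only ascent quantises modes). Bandwidth is `kernel_fraction` × the
larger side of the 5%-padded bounding box. Ascent stops when a point moves
less than 1e-3 × bandwidth (500-iteration cap; non-converged points are
labelled −1). Converged positions within 0.5 × bandwidth merge into one
mode; clusters are ordered by descending represented cell mass. The KDE is
weighted by landmark weights so density reflects cells, not landmarks.

## Drill-down semantics

AoIs overlap, so two conventions coexist deliberately:

* `expand_selection` keeps parent nodes whose summed influence on the
  selection reaches a threshold (default 0.5, which guarantees a node joins
  at most one of two disjoint selections; threshold 0 gives the exact AoI
  union) — the display-parity behaviour.
* `trace_to_data` assigns every node to its maximum-influence landmark
  (ties to the lower landmark id) and follows that ownership chain to the
  data level. For any partition of a level into disjoint selections this
  assigns every cell exactly once, which is what makes per-cluster cell
  counts well-defined without downsampling.

## Synthetic data

`make_mixture` emulates the statistical structure of gated CyTOF data:
Gaussian components in arcsinh space (hi/lo marker patterns at 0.5/2.5,
pairwise ≥ 6 noise SDs apart; noise SD 0.3), pushed through `sinh(·)×5` so
the raw output behaves like ion counts and the cofactor-5 transform
recovers the latent mixture exactly. The default rare component carries
0.5% of cells — the scale of the smallest disease-associated populations
highlighted in mass-cytometry studies. It does not model spillover,
doublets, bead events or acquisition drift, so passing tests speak to the
hierarchy/embedding machinery, not to instrument artefact handling.

`make_manifold3d` realises the Euclidean-vs-geodesic conflict with two
concentric half-cylinder sheets (radius 1 and 1.2, height 3, isotropic
noise SD 0.015). The geometry is chosen so that the conflict lives at the
*exploration* scale, as it does in practice: at full density (10,000
points) the kNN graph stays on-sheet, while at overview density (a few
hundred points — what a heavy downsample or the landmark set sees) around a
fifth of Euclidean nearest neighbours cross the 0.2 gap, although the
within-manifold neighbour is always same-sheet. A configuration in which
*full-density* nearest neighbours cross the gap was examined and rejected:
any such point faces the opposing 2-D sheet at its own neighbour distance,
so roughly half of its transition row leaves the sheet no matter how the
bandwidths are calibrated, the ambiguity is information-theoretically
unresolvable, and cross-sheet similarity then grows (not shrinks) up the
hierarchy. The sheets are analytic, so geodesic oracles use the intrinsic
`(r·θ, z)` coordinates returned by the generator. The manifold acceptance
configuration uses `k = 15`, `perplexity = 8` (k sized to the 10k sampling
density; the default `k = 100` neighbourhood radius would swallow the gap).

## Problem sizes in the tests

The acceptance suite builds one 100,000-cell, 3-level mixture hierarchy
(fast kNN backend) shared by the conservation, rare-population and
shrinkage checks, and one 10,000-point, 2-level manifold hierarchy (exact
kNN) for the structure-preservation checks; gradient oracles run at 500
points and the walk oracle at ≤ 200 nodes. These sizes exercise every code
path at full parameter settings while keeping the whole suite in the
minutes range.

## Known limitations

* The kNN backends are exact (brute force and tree search); a true
  approximate-NN index would be needed for tens of millions of cells and
  can be slotted in behind `build_knn`'s interface.
* Hierarchy construction is in-memory; there is no out-of-core path.
* FCS support covers list-mode FCS 3.0/3.1 with uniform bit width; log
  channel scaling (`$PnE`) is ignored with a warning, per mass-cytometry
  convention (linear channels).
* Embeddings are 2-D only.
* GMS mean shift is O(n²) per iteration in the number of embedded nodes;
  it is intended for overview levels (≲ 5,000 landmarks), which is how the
  level rule is designed to be used.
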