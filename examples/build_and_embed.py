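"""Build a landmark hierarchy over a synthetic CyTOF-like mixture and embed
the overview level.

A 20,000-cell Gaussian mixture (raw ion counts) is arcsinh-transformed with
cofactor 5, a two-level hierarchy is built with the standard walk parameters
(100 selection walks of length 15, 15 influence walks), and the overview
level is embedded with Barnes-Hut SNE.  The printed level sizes show the
roughly order-of-magnitude shrinkage per level; the KL trace shows the
embedding converging.
"""

import cytohsne as ch

data = ch.make_mixture(n_cells=20_000, seed=1)
m = ch.arcsinh_transform(data.matrix)

params = ch.HsneParams(n_levels=2, seed=1)
h = ch.build_hierarchy(m, params)
print("level sizes:", h.level_sizes)
print("shrinkage:", round(h.level_sizes[0] / h.level_sizes[1], 1), "x")
print("overview weight sum:", round(h.weights_at(1).sum(), 6), "(= n_cells, nothing lost)")

p = ch.joint_probabilities(h.transition_at(1))
emb = ch.tsne_embed(p, n_iter=1000, theta=0.5, seed=1)
print("KL divergence first/last:", round(emb.kl_trace[0], 3), "->", round(emb.kl_trace[-1], 3))
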