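"""Infer genetic clusters and linkage-disequilibrium summaries.

k-means over principal components picks the number of clusters at minimum
BIC; background LD is the chance (inter-chromosomal) r² level and the decay
curve's crossing of that level bounds the distance of genuine linkage.
"""

from curdpred import ld, simulate, structure

cfg = simulate.SimConfig(traits=())  # default density: 9 x 500 markers
G, truth = simulate.simulate_population(cfg, seed=5)

sol = structure.find_clusters(G, k_range=range(1, 9), seed=0)
print(f"inferred K = {sol.K} clusters (true 5)")

background = ld.background_ld(G, n_pairs=800, seed=0)
print(f"background LD r^2 (95th pct, inter-chromosomal) = {background:.3f}")

curve = ld.ld_decay(G, "C01", background=background, max_pairs=4000, seed=0)
if curve.intersection_bp:
    print(f"decay curve meets background at {curve.intersection_bp / 1e3:.0f} kb")
# Markers further apart than the crossing distance are no more correlated
# than markers on different chromosomes — linkage information is exhausted.
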