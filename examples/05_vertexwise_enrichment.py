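"""Vertex-wise bootstrap-ratio map and permutation network enrichment.

Computes, for every vertex, the sex-adjusted correlation of thickness with
executive function over 500 shared bootstrap resamples, forms the bootstrap
ratio (mean/SD of draws), counts vertices exceeding z-like thresholds per
network, and compares each network's count with a shuffled-BSR null.
"""

import numpy as np

from netcog import (
    NetworkCoupling, compute_composites, default_config, simulate_cohort,
    permutation_network_test, vertex_bootstrap_ratios,
)

tf = np.zeros((7, 2))
tf[6, 0] = 0.35
coupling = NetworkCoupling(tf, np.full(7, -0.2), np.zeros((7, 2)))
cohort = simulate_cohort(default_config(network_coupling=coupling, seed=13))
table, _, _ = compute_composites(cohort.participants)

bmap = vertex_bootstrap_ratios(
    cohort.thickness,
    table["executive_function"].to_numpy(),
    covariates=table["sex"].to_numpy(float)[:, None],
    B=500,
    seed=1,
    kind="correlation",
)
result = permutation_network_test(
    bmap, cohort.thickness.labels, thresholds=(1.96, 2.58, 3.3, 3.9),
    n_perm=2000, seed=2,
)

print("suprathreshold vertex counts (BSR >= t), with permutation null mean")
print("network  t=1.96 (null)      p_enriched")
for g in range(1, 8):
    c = result.counts.loc[g, 1.96]
    nm = result.null_mean.loc[g, 1.96]
    p = result.p_ge.loc[g, 1.96]
    print(f"  {g}      {c:5d} ({nm:7.1f})     {p:.4f}")

# Only the planted network should hold significantly more suprathreshold
# vertices than its share of a random reshuffling of the map (p ~ 0, at the
# 1/n_perm resolution of the test).
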