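"""Build the mutual-information network (MIN) and the distance network
(DN), then partition the MIN with Markov clustering.

MIN edges connect column pairs with z >= 6; DN edges connect residues
whose minimum heavy-atom distance is below 5 Å.  Markov clustering at the
modularity-maximizing inflation should cut the MIN into the planted
groups.
"""

from coevonet import (
    SyntheticConfig, build_dn, build_min, cluster_weights, filter_small_clusters,
    generate_msa, generate_structure, giant_component, modularity,
    permutation_zscores, select_inflation, trim_msa,
)

config = SyntheticConfig(seed=5)
msa, truth = generate_msa(config)
tmsa = trim_msa(msa)
mm = permutation_zscores(tmsa, cluster_weights(tmsa), n_perm=100, seed=6)

min_net = build_min(mm, threshold=6.0)
dn = build_dn(generate_structure(truth, seed=9), cutoff=5.0)
print(f"MIN: {min_net.number_of_nodes()} nodes, {min_net.number_of_edges()} edges "
      f"(giant component: {giant_component(min_net).number_of_nodes()} nodes)")
print(f"DN:  {dn.number_of_nodes()} nodes, {dn.number_of_edges()} edges")

inflation, cs = select_inflation(min_net)
q = modularity(min_net, cs)
cs = filter_small_clusters(cs, min_size=4)
print(f"selected inflation {inflation:.1f}, modularity {q:.3f}")
for cid, members in sorted(cs.clusters.items()):
    print(f"  MI cluster {cid}: {sorted(members)}")
print(f"planted groups:   {[sorted(g) for g in truth.coupled_groups]}")
# Clusters of size < 4 are discarded; the surviving MI clusters should match
# the planted groups (background columns end up unassigned or in loose
# residual clusters).
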