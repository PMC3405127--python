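"""Map MI clusters onto the structure: MI3D clusters, catalytic labels,
and the cluster contact network (3DCN).

An MI cluster's residues induce a subgraph of the DN; each connected
component with at least 4 residues is an MI3D cluster.  Clusters holding
(or touching, <5 Å) a catalytic residue are labelled catalytic.
"""

from coevonet import (
    SyntheticConfig, build_3dcn, build_dn, cluster_weights, filter_small_clusters,
    generate_msa, generate_structure, inter_cluster_coevolution_z, label_catalytic,
    map_to_structure, permutation_zscores, select_inflation, trim_msa, build_min,
)

config = SyntheticConfig(seed=21)
msa, truth = generate_msa(config)
tmsa = trim_msa(msa)
mm = permutation_zscores(tmsa, cluster_weights(tmsa), n_perm=100, seed=22)
_, cs = select_inflation(build_min(mm))
cs = filter_small_clusters(cs)

structure = generate_structure(truth, seed=23)
dn = build_dn(structure)

mi3d = []
for cid, members in sorted(cs.clusters.items()):
    for c in map_to_structure(members, dn, parent_id=cid):
        mi3d.append(label_catalytic(c, truth.catalytic_positions, structure))

for c in mi3d:
    tag = "catalytic" if c.catalytic else "non-catalytic"
    print(f"MI3D {c.cluster_id} ({tag}, parent MI cluster {c.parent_mi_cluster}): "
          f"{sorted(c.residues)}")

cn = build_3dcn(mi3d, structure)
print(f"3DCN: {cn.number_of_nodes()} clusters, {cn.graph.number_of_edges()} contacts")

if cn.graph.number_of_edges():
    a, b = sorted(cn.graph.edges)[0]
    obs, z = inter_cluster_coevolution_z(cn.clusters[a], cn.clusters[b], mm, seed=24)
    print(f"inter-cluster co-evolution {a}--{b}: observed coupled fraction "
          f"{obs:.2f}, z = {z:.1f} vs random residue sets")
# Only the cluster overlapping the planted catalytic blob should carry the
# catalytic label; 3DCN edges appear exactly where blobs were bridged.
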