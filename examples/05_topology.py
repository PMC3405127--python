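"""Topological characterization of a residue network.

Per-node metrics, degree-distribution fits (Poisson vs power law),
a degree-preserving rewired null, and Watts-Strogatz style small-world
reference values.
"""

from coevonet import (
    SyntheticConfig, build_dn, generate_msa, generate_structure,
    characteristic_path_length, fit_degree_distribution, giant_component,
    local_metrics, rewire_null, small_world_references,
)

config = SyntheticConfig(seed=31)
_, truth = generate_msa(config)
dn = giant_component(build_dn(generate_structure(truth, seed=32)))

metrics = local_metrics(dn)
print(f"DN giant component: {dn.number_of_nodes()} residues")
print(f"mean degree {metrics.degree.mean():.2f}, "
      f"mean clustering {metrics.clustering.mean():.3f}")
L = characteristic_path_length(dn)
print(f"characteristic path length L = {L:.2f}")

refs = small_world_references(dn)
print(f"random references:  C_random = {refs['C_random']:.3f}, "
      f"L_random = {refs['L_random']:.2f}")
print(f"regular references: C_regular = {refs['C_regular']:.3f}, "
      f"L_regular = {refs['L_regular']:.2f}")

fit = fit_degree_distribution(dn)
print(f"degree fit: verdict '{fit.verdict}' "
      f"(Poisson lambda {fit.lambda_hat:.2f}, KS p {fit.ks_p_poisson:.3f})")

null = rewire_null(dn, n_networks=200, seed=33)
print(f"rewired null (200 networks): C = {null.c_mean:.3f} +/- {null.c_sd:.3f}, "
      f"L = {null.l_mean:.2f} +/- {null.l_sd:.2f}")
# C far above C_random at comparable L signals small-world organisation;
# the rewired ensemble shows how much clustering the degree sequence alone
# would produce.
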