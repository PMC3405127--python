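"""Functional-feature enrichment of co-evolving clusters.

Feature annotations are placed in the planted groups at a controlled
odds ratio, projected through the alignment (>10% support rule), and the
enrichment of cluster residues is scored with odds ratios and Fisher
exact tests backed by a random-placement null.
"""

from coevonet import (
    SyntheticConfig, generate_annotations, generate_msa, map_features,
    odds_ratio, randomization_fisher, trim_msa,
)

config = SyntheticConfig(seed=51)
msa, truth = generate_msa(config)
catalytic_df, features_df = generate_annotations(
    truth, target_odds_ratio=4.0, seed=52, msa=msa
)
tmsa = trim_msa(msa)
table = map_features(features_df, tmsa, support=0.10)
print(f"features surviving the >10% support rule: "
      f"{sorted(table.features)} at {len(table.positions)} positions")

background = set(tmsa.reference_positions)
cluster = set().union(*truth.coupled_groups)  # planted-group residues
for feat in sorted(table.features):
    positions = table.positions_with(feat)
    res = randomization_fisher(positions, cluster, background, seed=53)
    orat = "undefined" if res.odds_ratio is None else f"{res.odds_ratio:.2f}"
    star = " *" if res.significant else ""
    print(f"{feat:8s} OR = {orat:>9s}  Fisher p = {res.fisher_p:.2e}  "
          f"empirical p = {res.empirical_p}{star}")
# Features were planted at a 4-fold odds ratio inside the co-evolving
# groups, so most should come out enriched and significant (alpha = 0.01).
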