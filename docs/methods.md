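# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package.  It states nothing the test suite
and `scripts/acceptance.py` do not themselves compute.

## Co-evolution scoring

**Weighted MI.** For columns *(i, j)* of the trimmed alignment, joint
counts over the 20 standard amino acids accumulate the redundancy weight
of every sequence carrying a residue at both columns.  Sequences gapped
(or carrying an ambiguity code — B, Z, X, U, O, J are treated as gaps
everywhere) at either column are excluded from that pair without
renormalizing the weights: the simplest contract, at the cost of slightly
different effective counts per pair.  A pseudocount λ is added to all 400
cells before normalization; λ = 0.05 by default (the customary low-count
correction for this estimator family), configurable.  MI is reported in
bits (log base 2).  The base is immaterial once z-scores are taken, but it
is fixed and documented so raw values are comparable across runs.

**APC.** `APC(i,j) = mean_MI(i,·) · mean_MI(j,·) / overall_mean_MI`,
`MIp = MI − APC`.  Means run over scored (non-missing, off-diagonal)
pairs; an all-zero matrix gets APC = 0.  Pairs with no usable sequence
are "missing": excluded from the means, from the output table and from
the network, rather than being zero-scored.

**Permutation z-scores.** Each of `n_perm` (default 100) replicates
shuffles every column independently across sequences and recomputes the
full MI + APC pipeline.  `z = (MIp_obs − mean_perm)/sd_perm` with the
sample (ddof = 1) standard deviation.  Weights are *not* recomputed for
replicates — column shuffling preserves column composition, and
recomputation would dominate runtime while changing nothing
systematically.  A zero permutation sd yields a +∞ sentinel when the
observed value exceeds the null mean, else 0, and is logged.

The z ≥ 6.0 edge threshold is the method's operating point, chosen for
high specificity; the acceptance suite verifies that on coupling-free
(column-shuffled) alignments fewer than 1% of pairs reach it.

## Alignment preparation

Trimming applies, in order: (1) drop columns gapped in the reference row;
(2) drop columns with > 50% gaps (strict); (3) drop sequences covering
< 50% of the reference length (strict).  Because step (3) changes column
gap fractions, the pass is iterated to a fixpoint; the first pass is the
canonical rule order and the fixpoint makes trimming idempotent, which the
one-pass formulation is not in edge cases.  The reference row is never
dropped.  Reference numbering is 1-based over the ungapped reference;
structure residue numbering is assumed to coincide with it (an explicit
offset table can be supplied where it does not).

Sequence identity is matches / (columns where both sequences carry a
standard residue) — insensitive to coverage differences, and 0 when no
such column exists.  Redundancy weights are 1/(cluster size) under
single-linkage clustering at identity ≥ 0.62; single linkage is
order-independent and reproducible, and on near-duplicate subfamilies it
gives weights indistinguishable from greedy Hobohm-style schemes.

## Networks

MIN edges are inclusive (z ≥ 6); DN edges are strict (< 5 Å minimum
heavy-atom distance, the upper limit for attractive van der Waals
contacts; 8 Å electrostatic contacts are deliberately out of scope).
"Heavy atom" means any ATOM-record atom whose element is not H/D; HETATM
records and waters are ignored, and altloc duplicates resolve to the
highest-occupancy copy.  Residues missing from the structure are absent
from the DN and are dropped (with a log entry) when MI clusters are
mapped.  Topological analysis focuses on the giant component; component
ties break toward the component containing the smallest node id.

## Markov clustering

The MCL implementation is self-contained: self-loops of weight 1 are
added before column normalization (standard regularization preventing
parity oscillation), expansion is the matrix square, inflation the
entrywise power with renormalization, entries below 1e-5 are pruned and
iteration stops when the matrix changes by < 1e-8 (max 200 iterations;
non-convergence returns the current interpretation with a warning).
Clusters are the supports of attractor rows (positive diagonal); a node
claimed by several attractors joins the one giving it more flow mass,
ties toward the smaller attractor id — which is what merges the symmetric
attractor pairs of, e.g., a single edge into one 2-node cluster.

Inflation is selected from the grid 1.2, 1.4, …, 5.0 by maximizing
Newman–Girvan modularity of the resulting partition (uncovered nodes
counted as singletons), ties toward smaller inflation.  Modularity is the
package's own partition-quality criterion throughout; it is undefined on
zero-edge graphs and raises.  MI clusters below 4 residues are discarded.

## Structural mapping

MI3D clusters are the DN-connected components of an MI cluster's
residues, again with the ≥ 4 filter (the size rule applies to the mapped
components as well as to the MI clusters).  Catalytic labelling uses the
same strict < 5 Å minimum-heavy-atom criterion as the DN, both for
membership ("contains a catalytic residue") and proximity ("close to
one").  Cluster ids are deterministic: parent id plus component index
ordered by smallest member.  3DCN edges require at least one contacting
inter-cluster residue pair.  The inter-cluster co-evolution z-score
compares the observed fraction of coupled (z ≥ threshold) inter-cluster
pairs with disjoint random residue subsets of the same sizes drawn from
the scored residues; a zero-variance null reports z = 0 with a flag.

## Topology

Local metrics are the Watts–Strogatz clustering coefficient and
betweenness normalized by 2/((n−1)(n−2)).  Characteristic path length is
the mean over connected unordered pairs (restricted to the giant
component when disconnected).  Degree distributions are fitted by maximum
likelihood: Poisson (λ̂ = mean degree) and a discrete power law via the
zeta-function likelihood with x_min fixed at 1 (a KS-minimizing x_min
scan exists as an option, off by default); each fit is compared to the
sample with a plain KS test — conservative on discrete data, accepted
deliberately for simplicity — and "followed" means not rejected at
α = 0.01.  The rewired null applies degree-preserving double-edge swaps
(10 accepted swaps per edge, rejecting self-loops and duplicates) to each
of 1000 replicates; rigid graphs that admit no swap return flagged copies
of the input.  Small-world references use the ring-lattice / Erdős–Rényi
conventions: `C_random = ⟨k⟩/n`, `L_random = ln n / ln⟨k⟩`,
`C_regular = 3(⟨k⟩−2)/(4(⟨k⟩−1))`, `L_regular = n/(2⟨k⟩)`.  Quantiles
(IQR, tertile binning) use linear-interpolation (type-7) percentiles.

## Enrichment

Per-sequence features (ACT_SITE, BINDING, METAL, SITE, MUTAGEN, MOD_RES)
are projected through each sequence's ungapped coordinates onto alignment
columns; a (position, feature) pair survives only with strictly more than
10% sequence support.  The odds ratio is (featured fraction in scope) /
(featured fraction in background).  Significance combines two views that
are reported side by side: the Fisher exact test (one-sided, enrichment
direction — matching the hypergeometric-tail reading of the procedure)
and an empirical p from 1000 uniform random re-placements of the featured
positions; the significance flag at α = 0.01 uses the exact test.
Degenerate 2×2 tables (a zero margin) report p = 1 with a flag.  Tertile
bins close on the upper side (≤ P33, ≤ P66); constant values put all
residues in MEDIUM with a flag.  Cross-family averages are unweighted
means excluding families where the ratio is undefined; no
multiple-testing correction is applied by default (a Benjamini–Hochberg
option would be a thin wrapper, deliberately not bundled into the
reported tables).

## Catalytic prediction

Predictors are normalized within each 3DCN: relative size and relative
degree divide by the network means, betweenness is the normalized
centrality.  A cluster is predicted catalytic when **all three**
predictors meet their thresholds (inclusive ≥).  Conjunction is the only
combination rule under which a single triple of "optimal thresholds" is a
meaningful operating point; defaults are 0.67 / 0.06 / 0.85 (relative
size / betweenness / relative degree).  The evaluation keeps the
historically used, non-standard ratio names: `paper_sensitivity =
TP/(TP+FP)` (textbook precision) and `paper_specificity = TN/(TN+FN)`
(textbook NPV); the field names make the convention explicit so the
numbers are not mistaken for recall and TNR.  F is their harmonic mean,
reported on both the 0–1 and ×100 scales; grid search scans the Cartesian
threshold grid pooling clusters across families, ties toward
lexicographically smallest thresholds.  A single-cluster network gets
relative predictors 1.0 and betweenness 0, flagged.

## Synthetic data: what it emulates, and what it does not

The generator realizes the statistical regime the method assumes:

* **Coupling** — each planted group carries a latent k-state variable per
  sequence (k = 4 by default, equiprobable); every group column maps each
  state to a distinct residue and emits it, substituted to a random other
  residue with probability ε (default 0.05).  This latent-state model was
  chosen over a Potts sampler because its noise-free MI has a closed form
  (log2 k bits), giving exact oracles for tests.
* **Background** — independent columns with a dominant residue
  (probability 0.4) and the rest uniform; ten subfamilies of three
  near-duplicate sequences (3% mutations) exercise the 62% redundancy
  weighting while keeping ≥ 400 effective sequences of 500 — the regime
  in which this MI estimator is reliable.  Gaps fall uniformly at 3%,
  never in the reference row.
* **Geometry** — a point-cloud chain: one pseudo-center plus two
  satellite heavy atoms per residue, blobs packed so all intra-blob
  minimum distances are < 5 Å, blob separation ≥ `blob_spacing`
  (default 12 Å) except for designed contact pairs bridged to < 5 Å.
  The realized geometry is verified exhaustively and a generation error
  is raised if a blob cannot be packed.  No stereochemical realism is
  attempted — the pipeline consumes only pairwise distances.
* **Layout** — each planted group gets its own blob; background residues
  fill blobs of 8; blobs are chained by designed contacts with the
  catalytic group (the first, 8-column group; two interior residues are
  catalytic) placed between the other planted groups, so the DN is
  connected and the pipeline's 3DCN has the catalytic cluster central.
* **Annotations** — features are placed with in-group probability equal
  to `target_odds_ratio` times the background probability, scaled to
  ~200 expected placements, then annotated in ~60% of sequences so the
  >10% support rule passes.  ACT_SITE marks the catalytic positions.

What passing tests on this generator do **not** show: robustness to
phylogenetic correlation beyond flat near-duplication, to alignment
errors, to gapped references, to heterogeneous family sizes, or to the
geometry of real folds (where contact density, surface/core asymmetry
and chain connectivity shape the DN).  Corpus-scale statements about
real families are therefore out of reach of this test bed by design.
One visible echo of the difference: because planted groups are
near-cliques in the MIN, the recovered odds-ratio estimator is biased
low when the planted scope is a large fraction of the background (the
background fraction then includes the enriched scope); the acceptance
experiment uses a 20-of-500 scope where the bias is ≈ −11%.

## Numerical and degenerate-input conventions

* Missing MI pairs propagate as NaN and are excluded from means,
  networks and tables.
* `mi_score` validates normalization to 1e-8; zero-probability terms
  contribute 0.
* MCL pruning 1e-5 / convergence 1e-8 / max 200 iterations, chosen for
  bitwise reproducibility on desk-scale graphs; all configurable.
* Empirical p-values use the (1 + hits)/(1 + n) estimator, never exactly 0.
* Every stochastic routine takes an explicit seed; the pipeline derives
  per-stage seeds from the master seed via `SeedSequence.spawn`, and the
  manifest (parameters, seeds, artifact sha256 checksums, no timestamps)
  is byte-identical across reruns.
* Problem sizes in the default test and acceptance runs — 500×50
  families, 100 permutations, 10–20 seeds per experiment, 1000 rewired
  replicates — are the package's chosen desk-scale study conditions;
  they recover every planted structure while keeping full runs in the
  minutes range.

## Known limitations

* The MIN built from a synthetic family also contains a sparse web of
  weakly correlated background columns (residual subfamily correlation);
  MCL collects them into residual clusters that dissolve on structural
  mapping.  This mirrors the method's reliance on the DN to purify
  clusters, but it means MIN-level statistics include that web.
* The discrete power-law KS p-values are conservative; "power_law"
  verdicts are therefore slightly lenient near the boundary.
* `inter_cluster_coevolution_z` samples its null rather than enumerating
  it; at very small protein sizes enumeration would be exact (the tests
  use enumeration as the oracle).
* The CLI covers file-based stage execution; corpus-scale batch
  orchestration is a plain loop left to the caller.
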