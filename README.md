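# coevonet

Co-evolution networks of protein families: detect clusters of co-evolving
residues in a multiple sequence alignment, map them onto the 3D structure
of a reference protein, characterize the resulting networks topologically,
measure their enrichment in functional residues, and predict which clusters
are catalytic.

## Who this is for

Structural bioinformaticians studying how evolutionary covariation between
alignment columns relates to physical contacts and functional sites in
enzyme families.  The package is a library first — every stage is an
importable function operating on plain containers (NumPy arrays, pandas
DataFrames, networkx graphs) — with a thin `coevonet` CLI for running the
stages from a shell, and a synthetic-family generator so the whole chain
can be exercised and validated without any external database.

## The method

For each pair of alignment columns *(i, j)* the co-evolution signal is
weighted mutual information

```
MI(i,j) = Σ_{a,b} p(a,b) · log2[ p(a,b) / (p(a) p(b)) ]
```

with sequence weights 1/(62%-identity cluster size), a λ = 0.05
pseudocount per cell, and sequences gapped at either column excluded.
Background signal is removed with the average product correction,
`MIp = MI − mean_i · mean_j / mean_all`, and `MIp` is standardized into a
z-score against alignments whose columns were independently shuffled
across sequences.

Two graphs are then built over reference residue positions:

* **MIN** — edge where z ≥ 6 (a threshold calibrated for high specificity);
* **DN** — edge where the minimum heavy-atom distance is < 5 Å.

The MIN is partitioned with a from-scratch Markov clustering (MCL)
implementation at the modularity-maximizing inflation; clusters with
fewer than 4 residues are discarded (**MI clusters**).  Each MI cluster is
projected onto the DN; its connected components of ≥ 4 residues are
**MI3D clusters**, labelled *catalytic* when they contain (or lie < 5 Å
from) a catalytic residue.  MI3D clusters in mutual contact form the
cluster network **3DCN**, whose topology (relative size, relative degree,
betweenness) feeds a threshold predictor of catalytic clusters evaluated
with `F = 2ss′/(s+s′)`, where `s = TP/(TP+FP)` and `s′ = TN/(TN+FN)`.

## Worked example

```
$ python examples/03_networks_and_clusters.py
MIN: 50 nodes, 90 edges (giant component: 25 nodes)
DN:  50 nodes, 163 edges
selected inflation 1.4, modularity 0.775
  MI cluster 0: [1, 2, 3, 4, 5, 6, 7, 8]
  MI cluster 1: [9, 10, 11, 12, 13, 14]
  MI cluster 2: [15, 16, 17, 18, 19, 20]
  MI cluster 3: [21, 26, 29, 30, 34, 38, 39, 41, 44, 46, 50]
  MI cluster 4: [22, 24, 25, 28, 31, 33, 35, 36, 37, 40, 42, 45, 48, 49]
planted groups:   [[1, 2, 3, 4, 5, 6, 7, 8], [9, 10, 11, 12, 13, 14], [15, 16, 17, 18, 19, 20]]
```

The generator planted three groups of latently coupled columns; MCL on
the z ≥ 6 network recovers each one exactly as an MI cluster (clusters 3
and 4 collect weakly correlated background columns and dissolve once
mapped onto the structure).  `examples/` holds one such narrative script
per capability — simulation, MI scoring, networks and clustering,
structural mapping, topology, enrichment, catalytic prediction, and the
full pipeline.

The same run from the shell:

```
coevonet run --seed 1234 --out-dir my_run     # synthetic family by default
coevonet prep my_run/msa.fasta                # or stage by stage
```

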