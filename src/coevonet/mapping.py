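"""Mapping co-evolution clusters onto the structure.

An MI cluster (community of the mutual-information network) is projected
onto the distance network: its residues induce a subgraph of the DN whose
connected components — when at least four residues large — become *MI3D
clusters*.  MI3D clusters containing a catalytic residue, or lying within
5 Å of one, are labelled catalytic.  MI3D clusters in mutual contact are
joined into the cluster-level contact network (3DCN).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .mi import MiMatrix
from .networks import ResidueNetwork, StructureModel, residue_min_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Mi3dCluster:
    """A spatially connected set of co-evolving residues."""

    cluster_id: str
    parent_mi_cluster: int
    residues: frozenset
    catalytic: bool | None = None

    @property
    def size(self) -> int:
        return len(self.residues)


@dataclass
class ClusterNetwork3D:
    """Contact graph whose nodes are MI3D cluster ids."""

    graph: nx.Graph
    clusters: dict[str, Mi3dCluster] = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()


def map_to_structure(
    mi_cluster_residues,
    dn: ResidueNetwork,
    min_size: int = 4,
    parent_id: int = 0,
) -> list[Mi3dCluster]:
    """Split an MI cluster into DN-connected components of size >= min_size.

    Residues absent from the DN (unresolved in the structure) are dropped
    with a log entry.  Component ids are ``"<parent>.<k>"`` with components
    ordered by their smallest residue.
    """
    residues = set(mi_cluster_residues)
    present = residues & set(dn.graph.nodes)
    missing = residues - present
    if missing:
        logger.info(
            "MI cluster %s: %d residues not resolvable in the structure: %s",
            parent_id, len(missing), sorted(missing),
        )
    sub = dn.graph.subgraph(present)
    comps = sorted((c for c in nx.connected_components(sub)), key=min)
    out = []
    k = 0
    for comp in comps:
        if len(comp) < min_size:
            continue
        out.append(
            Mi3dCluster(
                cluster_id=f"{parent_id}.{k}",
                parent_mi_cluster=parent_id,
                residues=frozenset(comp),
            )
        )
        k += 1
    return out


def label_catalytic(
    cluster: Mi3dCluster,
    catalytic_positions,
    structure: StructureModel,
    cutoff: float = 5.0,
) -> Mi3dCluster:
    """Flag a cluster catalytic if it contains a catalytic residue or any
    member lies strictly within ``cutoff`` Å (min heavy-atom distance) of
    one.  Returns a copy with the flag set."""
    catalytic_positions = set(catalytic_positions)
    if not catalytic_positions:
        logger.warning("empty catalytic position list: cluster flagged non-catalytic")
        return replace(cluster, catalytic=False)
    resolved = catalytic_positions & set(structure.coordinates)
    skipped = catalytic_positions - resolved
    if skipped:
        logger.info("catalytic positions unresolved in structure, skipped: %s", sorted(skipped))
    if cluster.residues & catalytic_positions:
        return replace(cluster, catalytic=True)
    for member in cluster.residues:
        if member not in structure.coordinates:
            continue
        for cat in resolved:
            d = residue_min_distance(
                structure.coordinates[member], structure.coordinates[cat]
            )
            if d < cutoff:
                return replace(cluster, catalytic=True)
    return replace(cluster, catalytic=False)


def build_3dcn(
    clusters: list[Mi3dCluster],
    structure: StructureModel,
    cutoff: float = 5.0,
) -> ClusterNetwork3D:
    """Edge between two MI3D clusters iff at least one inter-cluster residue
    pair is in contact (min heavy-atom distance < cutoff)."""
    if not clusters:
        raise ValueError("need at least one MI3D cluster")
    g = nx.Graph()
    for c in clusters:
        g.add_node(c.cluster_id)
    for ca, cb in itertools.combinations(clusters, 2):
        contact = False
        for ra in ca.residues:
            if ra not in structure.coordinates:
                continue
            for rb in cb.residues:
                if rb not in structure.coordinates:
                    continue
                if residue_min_distance(
                    structure.coordinates[ra], structure.coordinates[rb]
                ) < cutoff:
                    contact = True
                    break
            if contact:
                break
        if contact:
            g.add_edge(ca.cluster_id, cb.cluster_id)
    return ClusterNetwork3D(graph=g, clusters={c.cluster_id: c for c in clusters})


def _coupled_fraction(res_a, res_b, mi: MiMatrix, threshold: float) -> float:
    pairs = 0
    hits = 0
    for ra in res_a:
        for rb in res_b:
            pairs += 1
            z = mi.z_between(ra, rb)
            if np.isfinite(z) and z >= threshold:
                hits += 1
    return hits / pairs if pairs else 0.0


def inter_cluster_coevolution_z(
    cluster_a: Mi3dCluster,
    cluster_b: Mi3dCluster,
    mi: MiMatrix,
    threshold: float = 6.0,
    n_random: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Observed fraction of coupled (z >= threshold) inter-cluster residue
    pairs, standardized against random disjoint residue subsets of the same
    sizes drawn from the protein's scored residues.

    Returns ``(observed_fraction, z_score)``; a zero-variance null yields
    z = 0 with a log entry.
    """
    scored = list(mi.ref_positions)
    a = sorted(set(cluster_a.residues) & set(scored))
    b = sorted(set(cluster_b.residues) & set(scored))
    if not a or not b:
        raise ValueError("both clusters must contain scored residues")
    observed = _coupled_fraction(a, b, mi, threshold)
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(scored))
    null = np.empty(n_random)
    for r in range(n_random):
        pick = rng.choice(universe, size=len(a) + len(b), replace=False)
        null[r] = _coupled_fraction(pick[: len(a)], pick[len(a):], mi, threshold)
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        logger.info("inter-cluster co-evolution null has zero variance; z = 0")
        return observed, 0.0
    return observed, float((observed - null.mean()) / sd)


def write_mi3d_tsv(clusters: list[Mi3dCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tparent_mi_cluster\tresidue\tcatalytic\n")
        for c in sorted(clusters, key=lambda c: c.cluster_id):
            flag = "" if c.catalytic is None else int(bool(c.catalytic))
            for r in sorted(c.residues):
                fh.write(f"{c.cluster_id}\t{c.parent_mi_cluster}\t{r}\t{flag}\n")


def read_mi3d_tsv(path) -> list[Mi3dCluster]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str})
    out = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        flag = grp.catalytic.iloc[0]
        out.append(
            Mi3dCluster(
                cluster_id=str(cid),
                parent_mi_cluster=int(grp.parent_mi_cluster.iloc[0]),
                residues=frozenset(int(r) for r in grp.residue),
                catalytic=None if pd.isna(flag) else bool(int(flag)),
            )
        )
    return out


def write_3dcn_tsv(cn: ClusterNetwork3D, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_a\tcluster_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in cn.graph.edges):
            fh.write(f"{a}\t{b}\n")
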