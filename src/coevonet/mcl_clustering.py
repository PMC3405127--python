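"""Markov clustering (MCL) of residue networks, inflation selection and
partition quality.

MCL simulates flow through the graph by alternating expansion (matrix
powers of the column-stochastic transition matrix) with inflation
(entrywise powers followed by column renormalization).  Flow concentrates
inside dense regions and dries up between them; at convergence the matrix
is (nearly) idempotent and clusters are read off its attractor rows.

This implementation is self-contained and deterministic: self-loops of
weight 1 are added before normalization (standard regularization against
parity oscillation), small entries are pruned for reproducibility, and
overlapping attractor support is resolved by flow mass, then by smaller
cluster id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .networks import ResidueNetwork

logger = logging.getLogger(__name__)

DEFAULT_INFLATION_GRID = tuple(np.round(np.arange(1.2, 5.0 + 1e-9, 0.2), 1))
MIN_CLUSTER_SIZE = 4


@dataclass
class ClusterSet:
    """A disjoint family of node clusters plus unassigned (filtered) nodes."""

    clusters: dict[int, frozenset]
    unassigned: frozenset
    inflation: float
    iterations: int
    converged: bool = True
    min_size: int | None = None

    @property
    def node_to_cluster(self) -> dict:
        return {n: cid for cid, members in self.clusters.items() for n in members}

    def sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.clusters.items()}

    def all_nodes(self) -> frozenset:
        out: set = set(self.unassigned)
        for members in self.clusters.values():
            out |= members
        return frozenset(out)


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, ResidueNetwork) else net


def mcl(
    net,
    inflation: float,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ClusterSet:
    """Run MCL on an (unweighted) graph and return the node partition."""
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    g = _as_graph(net)
    nodes = sorted(g.nodes())
    n = len(nodes)
    if n == 0:
        raise DegenerateInputError("cannot cluster an empty graph")
    index = {v: i for i, v in enumerate(nodes)}
    m = np.eye(n)  # self-loops of weight 1
    for a, b in g.edges():
        if a != b:
            m[index[a], index[b]] = m[index[b], index[a]] = 1.0
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.linalg.matrix_power(m, expansion)
        new = np.power(new, inflation)
        new[new < prune_below] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        new /= colsum
        delta = float(np.abs(new - m).max())
        m = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; interpreting current matrix", max_iter)

    # attractors: rows with surviving diagonal flow
    attractors = np.nonzero(np.diag(m) > 0.0)[0]
    if attractors.size == 0:  # numerically extreme; fall back to row maxima
        attractors = np.unique(m.argmax(axis=0))
    assignment = np.full(n, -1, dtype=int)
    best_mass = np.full(n, -1.0)
    for rank, i in enumerate(attractors):
        support = np.nonzero(m[i] > 0.0)[0]
        for j in support:
            mass = m[i, j]
            if mass > best_mass[j] + 0.0:
                best_mass[j] = mass
                assignment[j] = rank
            # ties keep the earlier (smaller-id) attractor
    # any column with no attractor support joins its strongest attractor row
    for j in np.nonzero(assignment < 0)[0]:
        assignment[j] = int(m[attractors, j].argmax())

    raw: dict[int, set] = {}
    for j, rank in enumerate(assignment):
        raw.setdefault(int(rank), set()).add(nodes[j])
    clusters_sorted = sorted((min(members), members) for members in raw.values() if members)
    clusters = {cid: frozenset(members) for cid, (_, members) in enumerate(clusters_sorted)}
    return ClusterSet(
        clusters=clusters,
        unassigned=frozenset(),
        inflation=float(inflation),
        iterations=it,
        converged=converged,
    )


def modularity(net, clusters: ClusterSet) -> float:
    """Newman-Girvan modularity of the partition; uncovered nodes are singletons."""
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        raise DegenerateInputError("modularity is undefined on a zero-edge graph")
    covered: set = set()
    communities = []
    for _, members in sorted(clusters.clusters.items()):
        communities.append(set(members))
        covered |= set(members)
    for v in g.nodes():
        if v not in covered:
            communities.append({v})
    return float(nx.community.modularity(g, communities))


def select_inflation(net, candidates=DEFAULT_INFLATION_GRID) -> tuple[float, ClusterSet]:
    """Run MCL per candidate inflation; keep the partition maximizing
    modularity (ties -> smaller inflation)."""
    candidates = list(candidates)
    if not candidates:
        raise ConfigurationError("empty inflation candidate list")
    best: tuple[float, float, ClusterSet] | None = None
    for inf in sorted(candidates):
        cs = mcl(net, inflation=float(inf))
        q = modularity(net, cs)
        if best is None or q > best[0] + 1e-12:
            best = (q, float(inf), cs)
    assert best is not None
    return best[1], best[2]


def filter_small_clusters(cs: ClusterSet, min_size: int = MIN_CLUSTER_SIZE) -> ClusterSet:
    """Move clusters smaller than ``min_size`` to the unassigned pool."""
    kept = {}
    dropped: set = set(cs.unassigned)
    for cid, members in sorted(cs.clusters.items()):
        if len(members) >= min_size:
            kept[len(kept)] = members
        else:
            dropped |= set(members)
    if not kept:
        logger.warning("all clusters below min_size=%d; empty cluster set", min_size)
    return ClusterSet(
        clusters=kept,
        unassigned=frozenset(dropped),
        inflation=cs.inflation,
        iterations=cs.iterations,
        converged=cs.converged,
        min_size=min_size,
    )


def read_clusters_tsv(path) -> ClusterSet:
    clusters: dict[int, set] = {}
    unassigned: set = set()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            node, cid = line.split()
            node, cid = int(node), int(cid)
            if cid < 0:
                unassigned.add(node)
            else:
                clusters.setdefault(cid, set()).add(node)
    return ClusterSet(
        clusters={c: frozenset(m) for c, m in sorted(clusters.items())},
        unassigned=frozenset(unassigned),
        inflation=float("nan"),
        iterations=0,
    )


def write_clusters_tsv(cs: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tcluster_id\n")
        rows = [(n, cid) for cid, members in cs.clusters.items() for n in members]
        rows += [(n, -1) for n in cs.unassigned]
        for n, cid in sorted(rows):
            fh.write(f"{n}\t{cid}\n")
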