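"""Independent oracles used by the test suite.

Everything here is deliberately written as plain, naive code — separate
from the package implementations it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def reference_mcl(graph: nx.Graph, inflation: float, expansion: int = 2,
                  prune_below: float = 1e-5, max_iter: int = 200,
                  tol: float = 1e-8) -> set[frozenset]:
    """Textbook MCL written straight from the algorithm description:
    add self-loops, column-normalize, iterate expand/inflate/prune to
    idempotence, then read clusters as the supports of attractor rows
    (rows with positive diagonal), merging overlapping supports."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.eye(n)
    for u, v in graph.edges():
        if u != v:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(m, expansion) ** inflation
        new[new < prune_below] = 0.0
        s = new.sum(axis=0)
        s[s == 0] = 1.0
        new = new / s
        if np.abs(new - m).max() < tol:
            m = new
            break
        m = new
    supports = [set(np.nonzero(m[i] > 0)[0]) for i in range(n) if m[i, i] > 0]
    # merge overlapping supports into clusters
    merged: list[set] = []
    for s in supports:
        s = set(s)
        absorbed = []
        for existing in merged:
            if existing & s:
                s |= existing
                absorbed.append(existing)
        merged = [e for e in merged if e not in absorbed]
        merged.append(s)
    covered = set().union(*merged) if merged else set()
    for j in range(n):
        if j not in covered:
            merged.append({j})
    return {frozenset(nodes[j] for j in s) for s in merged}


def brute_force_mi(joint: np.ndarray) -> float:
    """Term-by-term MI of a normalized joint table, base 2."""
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    total = 0.0
    for a in range(joint.shape[0]):
        for b in range(joint.shape[1]):
            if joint[a, b] > 0:
                total += joint[a, b] * math.log2(joint[a, b] / (pi[a] * pj[b]))
    return total


def brute_force_apc(mi: np.ndarray) -> np.ndarray:
    """Direct formula: APC(i,j) = mean_i * mean_j / overall mean over
    off-diagonal entries; returns MIp."""
    L = mi.shape[0]
    col_means = np.array([
        np.mean([mi[i, k] for k in range(L) if k != i]) for i in range(L)
    ])
    overall = np.mean([mi[i, j] for i in range(L) for j in range(L) if i != j])
    out = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(L):
            if i != j:
                apc = col_means[i] * col_means[j] / overall if overall != 0 else 0.0
                out[i, j] = mi[i, j] - apc
    return out


def bfs_components(nodes, edges) -> list[set]:
    """Connected components by explicit breadth-first search."""
    adj: dict = {v: set() for v in nodes}
    for a, b in edges:
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    seen: set = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        queue = [start]
        comp = {start}
        seen.add(start)
        while queue:
            v = queue.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    comp.add(w)
                    queue.append(w)
        comps.append(comp)
    return comps


def pairwise_identity(a: str, b: str) -> float:
    """Column-by-column identity over both-residue columns."""
    gaps = set("-.BZXUOJ*")
    matches = 0
    total = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in gaps and y not in gaps:
            total += 1
            if x == y:
                matches += 1
    return matches / total if total else 0.0


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
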