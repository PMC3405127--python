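"""Topological characterization of residue and cluster networks.

Covers local metrics (degree, Watts-Strogatz clustering coefficient,
normalized betweenness), global metrics (characteristic path length),
maximum-likelihood degree-distribution fits (Poisson vs discrete power
law, compared with Kolmogorov-Smirnov tests), degree-preserving rewired
null ensembles, and the ring-lattice / Erdős–Rényi reference values used
to diagnose small-world structure:

    C_random  = <k> / n            L_random  = ln(n) / ln(<k>)
    C_regular = 3(<k>-2)/(4(<k>-1))  L_regular = n / (2<k>)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net  # note: nx.Graph.graph is the attribute dict, not a graph
    return getattr(net, "graph", net)


@dataclass
class DegreeFitRecord:
    """ML fits of the degree distribution and KS verdicts at level alpha."""

    n: int
    lambda_hat: float
    alpha_hat: float | None
    ks_p_poisson: float | None
    ks_p_power_law: float | None
    verdict: str  # poisson | power_law | both | neither | insufficient
    alpha_level: float
    power_law_degenerate: bool = False


@dataclass
class RewireSummary:
    """Mean +/- sd of clustering coefficient and path length over a
    degree-preserving rewired ensemble."""

    n_networks: int
    swaps_per_edge: int
    c_mean: float
    c_sd: float
    l_mean: float
    l_sd: float
    no_swap_flag: bool


def local_metrics(net) -> pd.DataFrame:
    """Per-node degree, normalized degree (k/<k>), clustering coefficient
    and normalized betweenness centrality."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise DegenerateInputError("empty graph")
    degree = dict(g.degree())
    mean_k = np.mean(list(degree.values()))
    clustering = nx.clustering(g)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    nodes = sorted(g.nodes())
    return pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "norm_degree": [degree[v] / mean_k if mean_k > 0 else 0.0 for v in nodes],
            "clustering": [clustering[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def characteristic_path_length(net) -> float:
    """Mean shortest-path length over unordered connected node pairs.

    Disconnected inputs are restricted to the giant component first.
    """
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise DegenerateInputError("path length needs >= 2 nodes")
    if not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        g = g.subgraph(comps[0])
        if g.number_of_nodes() < 2:
            raise DegenerateInputError("giant component has < 2 nodes")
    return float(nx.average_shortest_path_length(g))


def _poisson_ks(sample: np.ndarray, lam: float) -> float:
    hi = int(sample.max()) + 1
    xs = np.arange(0, hi + 1)
    cdf = stats.poisson.cdf(xs, lam)
    ecdf = np.searchsorted(np.sort(sample), xs, side="right") / sample.size
    d = float(np.abs(ecdf - cdf).max())
    return float(stats.kstwo.sf(d, sample.size))


def _zipf_ks(sample: np.ndarray, alpha: float) -> float:
    hi = int(sample.max()) + 1
    xs = np.arange(1, hi + 1)
    cdf = stats.zipf.cdf(xs, alpha)
    ecdf = np.searchsorted(np.sort(sample), xs, side="right") / sample.size
    d = float(np.abs(ecdf - cdf).max())
    return float(stats.kstwo.sf(d, sample.size))


def _fit_power_law_alpha(sample: np.ndarray) -> float:
    """Discrete power-law MLE with x_min = 1 (zeta-function likelihood)."""
    slog = float(np.log(sample).sum())
    n = sample.size

    def nll(a: float) -> float:
        return n * np.log(special.zeta(a, 1)) + a * slog

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 25.0), method="bounded")
    return float(res.x)


def fit_degree_distribution(net, alpha_level: float = 0.01, xmin_scan: bool = False) -> DegreeFitRecord:
    """Fit Poisson and discrete power-law models to the degree sample.

    Poisson: lambda_hat = mean degree (all nodes).  Power law: zeta MLE on
    degrees >= 1 with x_min fixed at 1 (an optional KS-minimizing x_min
    scan is available but off by default).  Each fit is compared to the
    empirical sample with a plain KS test; a model is "followed" when it is
    not rejected at ``alpha_level``.
    """
    g = _as_graph(net)
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    n = degrees.size
    if n < 20:
        return DegreeFitRecord(
            n=int(n), lambda_hat=float(degrees.mean()) if n else float("nan"),
            alpha_hat=None, ks_p_poisson=None, ks_p_power_law=None,
            verdict="insufficient", alpha_level=alpha_level,
        )
    lam = float(degrees.mean())
    p_pois = _poisson_ks(degrees, lam)

    positive = degrees[degrees >= 1]
    degenerate = positive.size < 2 or np.all(positive == positive[0])
    alpha_hat = None
    p_pl = None
    if positive.size >= 2 and not degenerate:
        if xmin_scan:
            alpha_hat, p_pl = _power_law_xmin_scan(positive)
        else:
            alpha_hat = _fit_power_law_alpha(positive)
            p_pl = _zipf_ks(positive, alpha_hat)
    elif degenerate:
        logger.info("degenerate degree sample: power-law fit skipped")

    pois_ok = p_pois >= alpha_level
    pl_ok = (p_pl is not None) and (p_pl >= alpha_level)
    if pois_ok and pl_ok:
        verdict = "both"
    elif pois_ok:
        verdict = "poisson"
    elif pl_ok:
        verdict = "power_law"
    else:
        verdict = "neither"
    return DegreeFitRecord(
        n=int(n), lambda_hat=lam, alpha_hat=alpha_hat,
        ks_p_poisson=p_pois, ks_p_power_law=p_pl,
        verdict=verdict, alpha_level=alpha_level,
        power_law_degenerate=bool(degenerate),
    )


def _power_law_xmin_scan(sample: np.ndarray) -> tuple[float, float]:
    """Clauset-style x_min scan: pick the x_min minimizing the KS distance.

    Returns the alpha fitted at the chosen x_min and the KS p-value of the
    tail sample (shifted so that x_min maps to 1 for the zeta likelihood).
    """
    best: tuple[float, float, float] | None = None  # (D, alpha, p)
    for xmin in np.unique(sample)[:-1]:
        tail = sample[sample >= xmin] - xmin + 1  # shift tail onto the >=1 lattice
        alpha = _fit_power_law_alpha(tail)
        p = _zipf_ks(tail, alpha)
        hi = int(tail.max()) + 1
        xs = np.arange(1, hi + 1)
        d = float(np.abs(
            np.searchsorted(np.sort(tail), xs, side="right") / tail.size
            - stats.zipf.cdf(xs, alpha)
        ).max())
        if best is None or d < best[0]:
            best = (d, alpha, p)
    assert best is not None
    return best[1], best[2]


def rewire_null(
    net,
    n_networks: int = 1000,
    swaps_per_edge: int = 10,
    seed: int = 0,
    return_graphs: bool = False,
):
    """Degree-preserving double-edge-swap null ensemble.

    Each replicate applies ``swaps_per_edge * m`` accepted swaps (attempts
    producing self-loops or duplicate edges are rejected).  Rigid graphs
    that admit no swap at all yield replicates equal to the input, with
    ``no_swap_flag`` set.
    """
    g = _as_graph(net)
    m = g.number_of_edges()
    if m < 2:
        raise DegenerateInputError("rewiring needs >= 2 edges")
    seeds = np.random.SeedSequence(seed).spawn(n_networks)
    c_vals = np.empty(n_networks)
    l_vals = np.empty(n_networks)
    graphs = []
    any_no_swap = False
    target = swaps_per_edge * m
    for r in range(n_networks):
        rng = np.random.default_rng(seeds[r])
        h = g.copy()
        edges = list(h.edges())
        done = 0
        attempts = 0
        max_attempts = 100 * target
        while done < target and attempts < max_attempts:
            attempts += 1
            i, j = rng.integers(0, len(edges), size=2)
            if i == j:
                continue
            u, v = edges[i]
            x, y = edges[j]
            if rng.random() < 0.5:
                x, y = y, x
            if len({u, v, x, y}) < 4:
                continue
            if h.has_edge(u, x) or h.has_edge(v, y):
                continue
            h.remove_edge(u, v)
            h.remove_edge(x, y)
            h.add_edge(u, x)
            h.add_edge(v, y)
            edges[i] = (u, x)
            edges[j] = (v, y)
            done += 1
        if done == 0:
            any_no_swap = True
        c_vals[r] = nx.average_clustering(h) if h.number_of_nodes() else 0.0
        l_vals[r] = characteristic_path_length(h)
        if return_graphs:
            graphs.append(h)
    summary = RewireSummary(
        n_networks=n_networks,
        swaps_per_edge=swaps_per_edge,
        c_mean=float(c_vals.mean()),
        c_sd=float(c_vals.std(ddof=1)) if n_networks > 1 else 0.0,
        l_mean=float(l_vals.mean()),
        l_sd=float(l_vals.std(ddof=1)) if n_networks > 1 else 0.0,
        no_swap_flag=any_no_swap,
    )
    if any_no_swap:
        logger.info("rewire_null: input admits no degree-preserving swap")
    return (summary, graphs) if return_graphs else summary


def small_world_references(net) -> dict[str, float]:
    """Reference C and L for matched random (ER) and regular (ring-lattice)
    networks, evaluated on the giant component."""
    g = _as_graph(net)
    if not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        g = g.subgraph(comps[0])
    n = g.number_of_nodes()
    mean_k = 2 * g.number_of_edges() / n if n else 0.0
    if mean_k <= 1:
        raise DegenerateInputError("small-world references need mean degree > 1")
    return {
        "C_random": mean_k / n,
        "L_random": float(np.log(n) / np.log(mean_k)),
        "C_regular": 3 * (mean_k - 2) / (4 * (mean_k - 1)),
        "L_regular": n / (2 * mean_k),
    }


def dispersion_iqr(values) -> float:
    """Inter-quartile range with linear-interpolation (type-7) quantiles."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 4:
        raise DegenerateInputError("IQR needs >= 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def topology_report(net, alpha_level: float = 0.01, rewire: RewireSummary | None = None) -> dict:
    """Aggregate per-network summary used by the pipeline's JSON artifact."""
    g = _as_graph(net)
    metrics = local_metrics(net)
    out: dict = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "mean_degree": float(metrics.degree.mean()),
        "mean_clustering": float(metrics.clustering.mean()),
        "median_clustering": float(metrics.clustering.median()),
        "clustering_iqr": (
            dispersion_iqr(metrics.clustering) if len(metrics) >= 4 else None
        ),
        "degree_fit": asdict(fit_degree_distribution(net, alpha_level=alpha_level)),
    }
    try:
        out["characteristic_path_length"] = characteristic_path_length(net)
    except DegenerateInputError:
        out["characteristic_path_length"] = None
    try:
        out["small_world_references"] = small_world_references(net)
    except DegenerateInputError:
        out["small_world_references"] = None
    if rewire is not None:
        out["rewired_null"] = asdict(rewire)
    return out
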