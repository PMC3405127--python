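"""Predicting catalytic MI3D clusters from 3DCN topology.

Within a cluster contact network (3DCN), catalytic clusters tend to be
larger, better connected and more central than non-catalytic ones.  A
cluster is predicted catalytic when all three predictors reach their
thresholds (conjunction, inclusive comparisons):

    relative size   = cluster size   / mean cluster size of the 3DCN
    relative degree = cluster degree / mean degree of the 3DCN
    betweenness     = normalized betweenness centrality in the 3DCN

Default thresholds: relative size 0.67, betweenness 0.06, relative degree
0.85.  Performance is summarized with an F-measure defined as the harmonic
mean of

    paper_sensitivity = TP / (TP + FP)    (textbook precision)
    paper_specificity = TN / (TN + FN)    (textbook NPV)

— the historically used, non-standard definitions; field names make the
convention explicit so they are not mistaken for recall/TNR.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .mapping import ClusterNetwork3D

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionThresholds:
    relative_size_min: float = 0.67
    betweenness_min: float = 0.06
    relative_degree_min: float = 0.85

    def __post_init__(self) -> None:
        for v in (self.relative_size_min, self.betweenness_min, self.relative_degree_min):
            if v < 0:
                raise ValueError("thresholds must be >= 0")


@dataclass
class PredictionReport:
    tp: int
    fp: int
    tn: int
    fn: int
    paper_sensitivity: float
    paper_specificity: float
    f_measure: float
    sensitivity_defined: bool = True

    @property
    def f_measure_percent(self) -> float:
        return 100.0 * self.f_measure

    @property
    def n_clusters(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def cluster_predictors(cn: ClusterNetwork3D) -> pd.DataFrame:
    """Per-cluster relative size, relative degree and betweenness."""
    g = cn.graph
    ids = sorted(g.nodes())
    if not ids:
        raise ValueError("empty cluster network")
    sizes = {cid: cn.clusters[cid].size for cid in ids}
    mean_size = float(np.mean(list(sizes.values())))
    degrees = dict(g.degree())
    mean_degree = float(np.mean(list(degrees.values())))
    if len(ids) < 2:
        logger.info("single-cluster 3DCN: relative predictors set to 1, betweenness 0")
        bet = {ids[0]: 0.0}
        rel_deg = {ids[0]: 1.0}
        rel_size = {ids[0]: 1.0}
    else:
        bet = nx.betweenness_centrality(g, normalized=True)
        rel_deg = {
            cid: (degrees[cid] / mean_degree if mean_degree > 0 else 1.0) for cid in ids
        }
        rel_size = {cid: sizes[cid] / mean_size for cid in ids}
    return pd.DataFrame(
        {
            "size": [sizes[c] for c in ids],
            "relative_size": [rel_size[c] for c in ids],
            "relative_degree": [rel_deg[c] for c in ids],
            "betweenness": [bet[c] for c in ids],
        },
        index=pd.Index(ids, name="cluster_id"),
    )


def predict(cn: ClusterNetwork3D, thresholds: PredictionThresholds = PredictionThresholds()) -> pd.Series:
    """Label each cluster catalytic iff all three predictors reach their
    thresholds (inclusive)."""
    pred = cluster_predictors(cn)
    labels = (
        (pred.relative_size >= thresholds.relative_size_min)
        & (pred.betweenness >= thresholds.betweenness_min)
        & (pred.relative_degree >= thresholds.relative_degree_min)
    )
    labels.name = "predicted_catalytic"
    return labels


def fmeasure(predicted, truth) -> PredictionReport:
    """Confusion counts and the harmonic-mean F of the two ratios above.

    ``predicted`` and ``truth`` are aligned mappings/Series of booleans.
    With no predicted-catalytic cluster the sensitivity ratio is undefined
    and treated as 0 (flagged); F = 0 whenever the two ratios sum to 0.
    """
    pred = pd.Series(predicted).astype(bool)
    true = pd.Series(truth).astype(bool)
    if set(pred.index) != set(true.index):
        raise ValueError("predicted and truth labels must cover the same clusters")
    true = true.reindex(pred.index)
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    tn = int((~pred & ~true).sum())
    fn = int((~pred & true).sum())
    sens_defined = (tp + fp) > 0
    sens = tp / (tp + fp) if sens_defined else 0.0
    spec = tn / (tn + fn) if (tn + fn) > 0 else 0.0
    f = 2 * sens * spec / (sens + spec) if (sens + spec) > 0 else 0.0
    if not sens_defined:
        logger.info("no predicted-catalytic clusters: sensitivity treated as 0")
    return PredictionReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        paper_sensitivity=sens, paper_specificity=spec,
        f_measure=f, sensitivity_defined=sens_defined,
    )


def f_of(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of the two ratios (0 when both are 0)."""
    if sensitivity + specificity == 0:
        return 0.0
    return 2 * sensitivity * specificity / (sensitivity + specificity)


@dataclass
class GridSearchResult:
    thresholds: PredictionThresholds
    f_measure: float
    report: PredictionReport
    n_evaluated: int
    table: pd.DataFrame = field(repr=False, default=None)


def grid_search(
    labelled_networks: list[tuple[ClusterNetwork3D, dict]],
    size_grid,
    betweenness_grid,
    degree_grid,
) -> GridSearchResult:
    """Exhaustive scan of the threshold grid, pooling clusters across
    families; ties resolved toward lexicographically smallest thresholds."""
    size_grid = sorted(size_grid)
    betweenness_grid = sorted(betweenness_grid)
    degree_grid = sorted(degree_grid)
    if not (size_grid and betweenness_grid and degree_grid):
        raise ConfigurationError("threshold grids must be non-empty")
    if not labelled_networks:
        raise ConfigurationError("need at least one labelled cluster network")

    frames = []
    for k, (cn, truth) in enumerate(labelled_networks):
        pred = cluster_predictors(cn)
        pred = pred.assign(truth=[bool(truth[c]) for c in pred.index])
        pred.index = [f"fam{k}:{c}" for c in pred.index]
        frames.append(pred)
    pooled = pd.concat(frames)

    best: tuple[float, tuple, PredictionReport] | None = None
    n_eval = 0
    for ts, tb, td in itertools.product(size_grid, betweenness_grid, degree_grid):
        labels = (
            (pooled.relative_size >= ts)
            & (pooled.betweenness >= tb)
            & (pooled.relative_degree >= td)
        )
        rep = fmeasure(labels, pooled.truth)
        n_eval += 1
        key = (ts, tb, td)
        if best is None or rep.f_measure > best[0] + 1e-12:
            best = (rep.f_measure, key, rep)
    assert best is not None
    f, (ts, tb, td), rep = best
    return GridSearchResult(
        thresholds=PredictionThresholds(ts, tb, td),
        f_measure=f,
        report=rep,
        n_evaluated=n_eval,
        table=pooled,
    )
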