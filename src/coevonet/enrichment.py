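"""Functional-feature enrichment of residue clusters.

Per-sequence feature annotations (ACT_SITE, BINDING, METAL, SITE, MUTAGEN,
MOD_RES) are projected through the alignment onto family positions; a
(position, feature) pair survives only if strictly more than 10% of the
sequences support it.  Enrichment of a feature in a residue scope is the
odds ratio

    OR = (featured fraction in scope) / (featured fraction in background)

attached to a Fisher exact test (one-sided, enrichment direction) plus an
empirical p-value from uniform random re-placements of the featured
positions.  For topology-binned residues (SMALL/MEDIUM/LARGE tertiles of
degree or clustering coefficient) per-bin odds ratios are averaged across
families and compared with a Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import TrimmedMsa
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

FEATURE_LABELS = ("ACT_SITE", "BINDING", "METAL", "SITE", "MUTAGEN", "MOD_RES")
SUPPORT_THRESHOLD = 0.10


@dataclass
class FeatureTable:
    """Family-level feature map after the support filter."""

    positions: dict[int, frozenset]  # reference position -> feature labels
    support: dict[tuple[int, str], float] = field(default_factory=dict)
    threshold: float = SUPPORT_THRESHOLD

    def positions_with(self, feature: str) -> frozenset:
        return frozenset(p for p, labels in self.positions.items() if feature in labels)

    @property
    def features(self) -> frozenset:
        out: set = set()
        for labels in self.positions.values():
            out |= set(labels)
        return frozenset(out)


@dataclass
class FisherResult:
    odds_ratio: float | None
    fisher_p: float
    empirical_p: float | None
    significant: bool
    table: tuple[int, int, int, int]  # (feat_in, nofeat_in, feat_out, nofeat_out)
    degenerate: bool = False


def read_features_tsv(path) -> pd.DataFrame:
    """Read per-sequence annotations: sequence_id, position, feature."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    expected = {"sequence_id", "position", "feature"}
    if not expected <= set(df.columns):
        raise ValueError(f"feature TSV must have columns {sorted(expected)}")
    return df


def write_features_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def map_features(
    annotations: pd.DataFrame,
    tmsa: TrimmedMsa,
    support: float = SUPPORT_THRESHOLD,
) -> FeatureTable:
    """Project sequence-local annotations onto reference positions.

    A (position, feature) pair is kept iff the fraction of kept sequences
    annotating that column with the feature is strictly greater than
    ``support``.  Annotations for sequences or positions outside the
    trimmed alignment are skipped with a log entry.
    """
    n_seq = tmsa.n_sequences
    counts: dict[tuple[int, str], set] = {}
    kept_ids = set(tmsa.ids)
    maps: dict[str, dict[int, int]] = {}
    skipped = 0
    for row in annotations.itertuples(index=False):
        sid, pos, feat = str(row.sequence_id), int(row.position), str(row.feature)
        if sid not in kept_ids:
            skipped += 1
            continue
        if sid not in maps:
            maps[sid] = tmsa.sequence_position_to_column(sid)
        col = maps[sid].get(pos)
        if col is None:
            skipped += 1
            continue
        refpos = tmsa.col_to_refpos[col]
        counts.setdefault((refpos, feat), set()).add(sid)
    if skipped:
        logger.info("map_features: %d annotations outside the trimmed alignment", skipped)

    positions: dict[int, set] = {}
    support_frac: dict[tuple[int, str], float] = {}
    for (refpos, feat), sids in counts.items():
        frac = len(sids) / n_seq
        if frac > support:
            positions.setdefault(refpos, set()).add(feat)
            support_frac[(refpos, feat)] = frac
    return FeatureTable(
        positions={p: frozenset(v) for p, v in positions.items()},
        support=support_frac,
        threshold=support,
    )


def odds_ratio(feature_positions, cluster_residues, background_residues) -> float | None:
    """(featured fraction in cluster) / (featured fraction in background).

    Returns ``None`` when no background residue carries the feature (the
    undefined case); raises on an empty cluster.
    """
    background = set(background_residues)
    cluster = set(cluster_residues)
    if not background:
        raise ValueError("background must be non-empty")
    if not cluster:
        raise ValueError("cluster must be non-empty")
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")
    featured = set(feature_positions) & background
    if not featured:
        return None
    p_cluster = len(featured & cluster) / len(cluster)
    p_background = len(featured) / len(background)
    return p_cluster / p_background


def randomization_fisher(
    feature_positions,
    cluster_residues,
    background_residues,
    n_random: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> FisherResult:
    """Fisher exact test plus an empirical random-placement p-value.

    The empirical null re-places the observed number of featured positions
    uniformly over the background ``n_random`` times and reports
    ``(1 + #{replicates with >= observed in-cluster count}) / (1 + n_random)``.
    Degenerate 2x2 tables (a zero margin) give p = 1 with a flag.
    """
    background = sorted(set(background_residues))
    cluster = set(cluster_residues) & set(background)
    featured = set(feature_positions) & set(background)
    feat_in = len(featured & cluster)
    feat_out = len(featured) - feat_in
    nofeat_in = len(cluster) - feat_in
    nofeat_out = len(background) - len(cluster) - feat_out
    table = (feat_in, nofeat_in, feat_out, nofeat_out)

    n_feat = len(featured)
    if n_feat == 0 or n_feat == len(background) or not cluster or len(cluster) == len(background):
        orat = odds_ratio(featured, cluster, background) if featured and cluster else None
        return FisherResult(
            odds_ratio=orat, fisher_p=1.0, empirical_p=None,
            significant=False, table=table, degenerate=True,
        )
    _, fisher_p = stats.fisher_exact(
        [[feat_in, nofeat_in], [feat_out, nofeat_out]], alternative="greater"
    )
    rng = np.random.default_rng(seed)
    arr = np.array(background)
    in_cluster = np.isin(arr, sorted(cluster))
    hits = 0
    for _ in range(n_random):
        placed = rng.choice(len(arr), size=n_feat, replace=False)
        if int(in_cluster[placed].sum()) >= feat_in:
            hits += 1
    empirical_p = (1 + hits) / (1 + n_random)
    orat = odds_ratio(featured, cluster, background)
    return FisherResult(
        odds_ratio=orat,
        fisher_p=float(fisher_p),
        empirical_p=float(empirical_p),
        significant=bool(fisher_p < alpha),
        table=table,
    )


def bin_by_percentile(values: dict, cuts=(33.0, 66.0)) -> tuple[dict, bool]:
    """Tertile assignment of per-residue values: SMALL (<= P33),
    MEDIUM (P33 < v <= P66), LARGE (> P66); type-7 percentiles.

    Returns (assignment, degenerate_flag); a constant vector puts every
    residue in MEDIUM with the flag set.
    """
    if len(values) < 3:
        raise DegenerateInputError("binning needs >= 3 residues")
    arr = np.array(list(values.values()), dtype=float)
    if np.all(arr == arr[0]):
        logger.info("bin_by_percentile: constant values; all MEDIUM")
        return {k: "MEDIUM" for k in values}, True
    p33, p66 = np.percentile(arr, cuts)
    out = {}
    for k, v in values.items():
        if v <= p33:
            out[k] = "SMALL"
        elif v <= p66:
            out[k] = "MEDIUM"
        else:
            out[k] = "LARGE"
    return out, False


BIN_ORDER = ("SMALL", "MEDIUM", "LARGE")


@dataclass
class BinnedEnrichment:
    per_bin_mean_or: dict[str, float | None]
    per_bin_family_ors: dict[str, list[float]]
    kruskal_p: float | None
    n_families: int


def binned_enrichment(families: list[dict]) -> BinnedEnrichment:
    """Cross-family enrichment of a feature over topology tertiles.

    ``families`` holds one dict per family with keys ``feature_positions``,
    ``bins`` (residue -> SMALL/MEDIUM/LARGE) and ``scope`` (residues of the
    family's clusters).  Per family and bin the odds ratio is the featured
    fraction in the bin over the featured fraction in the whole scope;
    undefined or empty-bin cases are excluded.  The Kruskal-Wallis test
    compares the three bins' per-family odds-ratio samples (requires >= 5
    families with usable values).
    """
    per_bin: dict[str, list[float]] = {b: [] for b in BIN_ORDER}
    for fam in families:
        scope = set(fam["scope"])
        featured = set(fam["feature_positions"]) & scope
        if not scope or not featured:
            continue
        p_scope = len(featured) / len(scope)
        for b in BIN_ORDER:
            members = {r for r, lab in fam["bins"].items() if lab == b and r in scope}
            if not members:
                logger.info("binned_enrichment: empty %s bin excluded", b)
                continue
            per_bin[b].append((len(featured & members) / len(members)) / p_scope)

    mean_or = {
        b: (float(np.mean(v)) if v else None) for b, v in per_bin.items()
    }
    samples = [v for v in per_bin.values() if v]
    n_families = len(families)
    kruskal_p = None
    if len(samples) >= 2 and min(len(s) for s in samples) >= 5:
        try:
            _, kruskal_p = stats.kruskal(*samples)
            kruskal_p = float(kruskal_p)
        except ValueError:  # all values identical
            kruskal_p = 1.0
    return BinnedEnrichment(
        per_bin_mean_or=mean_or,
        per_bin_family_ors=per_bin,
        kruskal_p=kruskal_p,
        n_families=n_families,
    )
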