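"""End-to-end orchestration: alignment preparation -> mutual information ->
networks -> clustering -> structural mapping -> topology -> enrichment ->
catalytic prediction, with deterministic seeding and a run manifest.

Every stage writes its artifact under the output directory; the manifest
records all parameters, the derived per-stage seeds, stage bookkeeping
counts and a sha256 checksum per artifact, so two runs with the same
master seed and parameters produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import alignment, enrichment, mapping, mcl_clustering as mcl, mi, networks, prediction, synthetic, topology
from .errors import CoevonetError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run.

    Either the four input paths or ``synthetic`` must be provided.  The
    defaults are the canonical operating point of the method: z-score
    threshold 6.0, 5 Å contact cutoff, minimum cluster size 4, 62%
    identity weighting, >10% feature support, prediction thresholds
    0.67 / 0.06 / 0.85.
    """

    out_dir: str = "coevonet_run"
    msa_path: str | None = None
    msa_format: str = "fasta"
    structure_path: str | None = None
    catalytic_path: str | None = None
    features_path: str | None = None
    reference_id: str = "ref"
    chain_id: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    target_odds_ratio: float = 4.0

    identity_threshold: float = 0.62
    lam: float = 0.05
    n_perm: int = 100
    z_threshold: float = 6.0
    distance_cutoff: float = 5.0
    min_cluster_size: int = 4
    inflation_candidates: tuple = mcl.DEFAULT_INFLATION_GRID
    support: float = 0.10
    n_random: int = 1000
    rewire_networks: int = 1000
    thresholds: prediction.PredictionThresholds = field(
        default_factory=prediction.PredictionThresholds
    )
    seed: int = 0

    def parameter_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["inflation_candidates"] = [float(x) for x in self.inflation_candidates]
        d.pop("out_dir")
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    names = ("simulate_msa", "simulate_structure", "simulate_annotations",
             "mi", "enrichment", "rewire", "intercluster")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    counts: dict = {}
    artifacts: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(path)
        return path

    # --- stage: inputs (synthetic or files) -----------------------------
    truth = None
    if config.synthetic is not None:
        cfg = dataclasses.replace(config.synthetic, seed=seeds["simulate_msa"])
        msa, truth = synthetic.generate_msa(cfg)
        structure = synthetic.generate_structure(truth, seed=seeds["simulate_structure"])
        catalytic_df, features_df = synthetic.generate_annotations(
            truth, config.target_odds_ratio, seed=seeds["simulate_annotations"], msa=msa
        )
        emit("msa.fasta", lambda p: synthetic.write_msa_fasta(msa, p))
        emit("structure.pdb", lambda p: synthetic.write_structure_pdb(structure, p))
        emit("catalytic.tsv", lambda p: synthetic.write_catalytic_tsv(catalytic_df, p))
        emit("features.tsv", lambda p: enrichment.write_features_tsv(features_df, p))
        emit("ground_truth.json", truth.to_json)
    else:
        if not (config.msa_path and config.structure_path):
            raise CoevonetError("need msa_path and structure_path (or a synthetic config)")
        msa = alignment.read_msa(config.msa_path, config.msa_format, config.reference_id)
        structure = networks.read_pdb(config.structure_path, chain_id=config.chain_id)
        catalytic_df = (
            synthetic.read_catalytic_tsv(config.catalytic_path)
            if config.catalytic_path else None
        )
        features_df = (
            enrichment.read_features_tsv(config.features_path)
            if config.features_path else None
        )
    catalytic_positions = (
        set(catalytic_df["position"].astype(int)) if catalytic_df is not None else set()
    )

    # --- stage: alignment preparation -----------------------------------
    tmsa = alignment.trim_msa(msa)
    weights = alignment.cluster_weights(tmsa, threshold=config.identity_threshold)
    emit("column_map.tsv", lambda p: alignment.write_column_map_tsv(tmsa, p))
    emit("weights.tsv", lambda p: alignment.write_weights_tsv(weights, p))
    counts["sequences_kept"] = tmsa.n_sequences
    counts["columns_kept"] = tmsa.n_columns
    counts["effective_sequences"] = round(weights.effective_sequences, 6)

    # --- stage: mutual information --------------------------------------
    mm = mi.permutation_zscores(
        tmsa, weights, lam=config.lam, n_perm=config.n_perm, seed=seeds["mi"]
    )
    emit("mi_pairs.tsv", lambda p: mi.write_mi_tsv(mm, p))

    # --- stage: networks --------------------------------------------------
    min_net = networks.build_min(mm, threshold=config.z_threshold)
    dn = networks.build_dn(structure, cutoff=config.distance_cutoff)
    emit("min_edges.tsv", lambda p: networks.write_edge_list_tsv(min_net, p))
    emit("dn_edges.tsv", lambda p: networks.write_edge_list_tsv(dn, p))
    counts["min_edges"] = min_net.number_of_edges()
    counts["dn_edges"] = dn.number_of_edges()

    # --- stage: clustering ------------------------------------------------
    if min_net.number_of_edges() == 0:
        raise CoevonetError("clustering: the mutual-information network has no edges")
    inflation, cs = mcl.select_inflation(min_net, candidates=config.inflation_candidates)
    q = mcl.modularity(min_net, cs)
    cs_f = mcl.filter_small_clusters(cs, min_size=config.min_cluster_size)
    emit("mi_clusters.tsv", lambda p: mcl.write_clusters_tsv(cs_f, p))
    emit("clustering.json", lambda p: p.write_text(json.dumps({
        "inflation": inflation, "iterations": cs.iterations,
        "modularity": q, "n_clusters": len(cs_f.clusters),
        "discarded_small": len(cs.clusters) - len(cs_f.clusters),
    }, sort_keys=True, indent=1)))
    counts["mi_clusters"] = len(cs_f.clusters)
    counts["modularity"] = round(q, 6)
    counts["inflation"] = inflation

    # --- stage: structural mapping ---------------------------------------
    mi3d: list[mapping.Mi3dCluster] = []
    for cid, members in sorted(cs_f.clusters.items()):
        comps = mapping.map_to_structure(
            members, dn, min_size=config.min_cluster_size, parent_id=cid
        )
        mi3d.extend(
            mapping.label_catalytic(
                c, catalytic_positions, structure, cutoff=config.distance_cutoff
            )
            for c in comps
        )
    emit("mi3d_clusters.tsv", lambda p: mapping.write_mi3d_tsv(mi3d, p))
    counts["mi3d_clusters"] = len(mi3d)
    counts["catalytic_mi3d_clusters"] = sum(bool(c.catalytic) for c in mi3d)

    cn = None
    if mi3d:
        cn = mapping.build_3dcn(mi3d, structure, cutoff=config.distance_cutoff)
        emit("3dcn_edges.tsv", lambda p: mapping.write_3dcn_tsv(cn, p))

    # --- stage: topology --------------------------------------------------
    topo: dict = {}
    min_giant = networks.giant_component(min_net)
    for name, net in (("MIN_giant", min_giant), ("DN", dn)):
        rew = None
        if net.number_of_edges() >= 2:
            rew = topology.rewire_null(
                net, n_networks=config.rewire_networks, seed=seeds["rewire"]
            )
        topo[name] = topology.topology_report(net, rewire=rew)
    if cn is not None and cn.number_of_nodes() > 0:
        topo["3DCN"] = topology.topology_report(cn)
    emit("topology.json", lambda p: p.write_text(json.dumps(topo, sort_keys=True, indent=1)))

    # --- stage: enrichment ------------------------------------------------
    enrich_out: dict = {}
    if features_df is not None and len(features_df):
        ftable = enrichment.map_features(features_df, tmsa, support=config.support)
        background = set(tmsa.reference_positions)
        scopes = {
            "mi_clusters": set().union(*cs_f.clusters.values()) if cs_f.clusters else set(),
            "mi3d_clusters": set().union(*(c.residues for c in mi3d)) if mi3d else set(),
            "catalytic_mi3d": set().union(
                *(c.residues for c in mi3d if c.catalytic), set()
            ),
            "non_catalytic_mi3d": set().union(
                *(c.residues for c in mi3d if not c.catalytic), set()
            ),
        }
        for scope_name, scope in scopes.items():
            scope = scope & background
            if not scope:
                continue
            per_feature = {}
            for feat in sorted(ftable.features):
                res = enrichment.randomization_fisher(
                    ftable.positions_with(feat), scope, background,
                    n_random=config.n_random, seed=seeds["enrichment"],
                )
                per_feature[feat] = {
                    "odds_ratio": res.odds_ratio,
                    "fisher_p": res.fisher_p,
                    "empirical_p": res.empirical_p,
                    "significant": res.significant,
                    "table": list(res.table),
                }
            enrich_out[scope_name] = per_feature
    emit("enrichment.json", lambda p: p.write_text(
        json.dumps(enrich_out, sort_keys=True, indent=1)
    ))

    # --- stage: prediction ------------------------------------------------
    pred_out: dict = {}
    if cn is not None and cn.number_of_nodes() > 0:
        predictors = prediction.cluster_predictors(cn)
        labels = prediction.predict(cn, config.thresholds)
        pred_out["thresholds"] = dataclasses.asdict(config.thresholds)
        pred_out["clusters"] = {
            cid: {
                "relative_size": float(predictors.relative_size[cid]),
                "relative_degree": float(predictors.relative_degree[cid]),
                "betweenness": float(predictors.betweenness[cid]),
                "predicted_catalytic": bool(labels[cid]),
                "true_catalytic": (
                    None if cn.clusters[cid].catalytic is None
                    else bool(cn.clusters[cid].catalytic)
                ),
            }
            for cid in sorted(cn.clusters)
        }
        truth_labels = {cid: cn.clusters[cid].catalytic for cid in cn.clusters}
        if all(v is not None for v in truth_labels.values()):
            rep = prediction.fmeasure(labels, truth_labels)
            pred_out["report"] = {
                "tp": rep.tp, "fp": rep.fp, "tn": rep.tn, "fn": rep.fn,
                "paper_sensitivity": rep.paper_sensitivity,
                "paper_specificity": rep.paper_specificity,
                "f_measure": rep.f_measure,
                "f_measure_percent": rep.f_measure_percent,
            }
    emit("prediction.json", lambda p: p.write_text(
        json.dumps(pred_out, sort_keys=True, indent=1)
    ))

    manifest = {
        "package_version": __version__,
        "parameters": config.parameter_dict(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "counts": counts,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
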