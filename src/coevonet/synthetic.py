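"""Synthetic protein families with planted co-evolution signal.

The generator emulates the statistical structure the analysis assumes,
so every downstream stage can be exercised and scored without external
databases:

* an MSA in which each *planted group* of columns is driven by a latent
  per-sequence state (k equiprobable states, one state-specific residue
  per column, substituted to a random other residue with probability
  ``noise``), background columns are independent with a tunable dominant
  residue probability, a few subfamilies of near-duplicate sequences
  exercise the 62%-identity weighting, and gaps are sprinkled uniformly
  (never in the reference row);
* a point-cloud structure in which each planted group occupies a compact
  blob (all pairwise minimum heavy-atom distances < 5 Å), different blobs
  are kept at least ``blob_spacing`` apart except for designed contact
  pairs bridged to < 5 Å, so the distance network is known exactly;
* catalytic positions inside exactly one planted blob, and feature
  annotations placed in planted groups at a controlled odds ratio.

A :class:`GroundTruth` manifest records everything needed to score
recovery.  All three generators are fully deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, Msa
from .errors import ConfigurationError, GenerationError
from .mapping import ClusterNetwork3D, Mi3dCluster
from .networks import StructureModel

N_AA = 20
_BLOB_RADIUS = 1.8  # Å, residue centers packed within this ball
_SATELLITE = 0.4  # Å, satellite heavy atoms this far from the center
_MIN_SEP = 0.5  # Å, minimum center separation inside a blob

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class PlantedGroup:
    """A set of columns coupled through a shared latent state."""

    columns: tuple  # 0-based column indices
    n_states: int = 4
    noise: float = 0.05


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic family.

    Defaults follow the regime the analysis is designed for: 500 sequences
    (>= 400 effective after redundancy weighting), three planted groups of
    8 + 6 + 6 columns with 4 latent states and 5% emission noise, moderate
    background conservation, sparse gaps and ten small subfamilies of
    near-duplicates.
    """

    n_sequences: int = 500
    n_columns: int = 50
    planted_groups: tuple = (
        PlantedGroup(columns=tuple(range(0, 8))),
        PlantedGroup(columns=tuple(range(8, 14))),
        PlantedGroup(columns=tuple(range(14, 20))),
    )
    background_conservation: float = 0.4
    gap_rate: float = 0.03
    n_subfamilies: int = 10
    subfamily_size: int = 3
    subfamily_mutation_rate: float = 0.03
    background_blob_size: int = 8
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_sequences, self.n_columns, self.n_subfamilies, self.subfamily_size) < 1:
            raise ConfigurationError("all counts must be positive")
        if not (0.0 <= self.background_conservation <= 1.0):
            raise ConfigurationError("background_conservation must be in [0,1]")
        if not (0.0 <= self.gap_rate <= 1.0):
            raise ConfigurationError("gap_rate must be in [0,1]")
        seen: set = set()
        for g in self.planted_groups:
            if not (0.0 <= g.noise < 0.5):
                raise ConfigurationError("group noise must be in [0, 0.5)")
            if g.n_states < 2 or g.n_states > N_AA:
                raise ConfigurationError("latent state count must be in [2, 20]")
            for c in g.columns:
                if not (0 <= c < self.n_columns):
                    raise ConfigurationError(
                        f"planted group references column {c} >= n_columns={self.n_columns}"
                    )
                if c in seen:
                    raise ConfigurationError("planted column sets must be disjoint")
                seen.add(c)
        n_dup = self.n_subfamilies * (self.subfamily_size - 1)
        if self.n_sequences - n_dup < max(2, self.n_subfamilies + 1):
            raise ConfigurationError("too few base sequences for the requested subfamilies")


@dataclass
class GroundTruth:
    """Manifest of everything the generators planted."""

    coupled_groups: list  # list of frozensets of reference positions
    blob_assignment: dict  # reference position -> blob id
    catalytic_positions: frozenset
    feature_placements: dict = field(default_factory=dict)  # label -> frozenset
    designed_contacts: frozenset = frozenset()  # inter-blob (refpos, refpos) pairs
    catalytic_blob: int = 0

    def validate(self) -> None:
        blobs_hit = {self.blob_assignment[p] for p in self.catalytic_positions}
        if len(blobs_hit) != 1:
            raise ConfigurationError("catalytic positions must lie in exactly one blob")
        for group in self.coupled_groups:
            for p in group:
                if p not in self.blob_assignment:
                    raise ConfigurationError(f"planted position {p} has no structural residue")

    def blob_members(self) -> dict:
        out: dict = {}
        for pos, bid in self.blob_assignment.items():
            out.setdefault(bid, set()).add(pos)
        return {bid: frozenset(v) for bid, v in out.items()}

    def to_json(self, path) -> None:
        payload = {
            "coupled_groups": [sorted(g) for g in self.coupled_groups],
            "blob_assignment": {str(k): v for k, v in sorted(self.blob_assignment.items())},
            "catalytic_positions": sorted(self.catalytic_positions),
            "feature_placements": {k: sorted(v) for k, v in sorted(self.feature_placements.items())},
            "designed_contacts": sorted(map(list, self.designed_contacts)),
            "catalytic_blob": self.catalytic_blob,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            coupled_groups=[frozenset(g) for g in p["coupled_groups"]],
            blob_assignment={int(k): int(v) for k, v in p["blob_assignment"].items()},
            catalytic_positions=frozenset(p["catalytic_positions"]),
            feature_placements={k: frozenset(v) for k, v in p["feature_placements"].items()},
            designed_contacts=frozenset(tuple(x) for x in p["designed_contacts"]),
            catalytic_blob=int(p["catalytic_blob"]),
        )


def _build_blob_layout(config: SyntheticConfig) -> GroundTruth:
    """Assign every reference position to a blob and plant the catalytic site.

    Each planted group gets its own blob; background positions are chunked
    into blobs.  The chain order places the catalytic group between the
    other planted groups, with background blobs at the ends, and designed
    contacts bridge consecutive blobs so the distance network is connected.
    """
    groups = [frozenset(c + 1 for c in g.columns) for g in config.planted_groups]
    group_cols = set().union(*groups) if groups else set()
    background = [p for p in range(1, config.n_columns + 1) if p not in group_cols]
    bg_blobs = [
        frozenset(background[i : i + config.background_blob_size])
        for i in range(0, len(background), config.background_blob_size)
    ]
    # catalytic group (index 0) in the middle of the group run
    order = list(range(len(groups)))
    if order:
        order.remove(0)
        order.insert(len(order) // 2, 0)
    chain: list = []
    if bg_blobs:
        chain.append(bg_blobs[0])
    chain.extend(groups[i] for i in order)
    chain.extend(bg_blobs[1:])

    blob_assignment = {}
    for bid, members in enumerate(chain):
        for p in members:
            blob_assignment[p] = bid

    cat_group = sorted(groups[0]) if groups else sorted(chain[0])
    catalytic = frozenset(cat_group[1:3])  # interior members, never bridge residues
    catalytic_blob = blob_assignment[cat_group[1]]

    contacts = set()
    for k in range(len(chain) - 1):
        left = sorted(set(chain[k]) - catalytic)
        right = sorted(set(chain[k + 1]) - catalytic)
        contacts.add((left[-1], right[0]))

    gt = GroundTruth(
        coupled_groups=groups,
        blob_assignment=blob_assignment,
        catalytic_positions=catalytic,
        designed_contacts=frozenset(contacts),
        catalytic_blob=catalytic_blob,
    )
    gt.validate()
    return gt


def generate_msa(config: SyntheticConfig) -> tuple[Msa, GroundTruth]:
    """Sample the family alignment and its ground-truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_dup = config.n_subfamilies * (config.subfamily_size - 1)
    n_base = config.n_sequences - n_dup
    L = config.n_columns

    # background emission: one dominant residue per column
    dominant = rng.integers(0, N_AA, size=L)
    base = np.empty((n_base, L), dtype=np.int8)
    hit = rng.random((n_base, L)) < config.background_conservation
    other = rng.integers(0, N_AA - 1, size=(n_base, L))
    other = other + (other >= dominant[np.newaxis, :])
    base[:] = np.where(hit, dominant[np.newaxis, :], other)

    # planted groups: latent state -> distinct residue per column
    for g in config.planted_groups:
        perms = np.vstack([rng.permutation(N_AA)[: g.n_states] for _ in g.columns])
        states = rng.integers(0, g.n_states, size=n_base)
        for k, c in enumerate(g.columns):
            emitted = perms[k, states]
            noisy = rng.random(n_base) < g.noise
            sub = rng.integers(0, N_AA - 1, size=n_base)
            sub = sub + (sub >= emitted)
            base[:, c] = np.where(noisy, sub, emitted)

    # subfamilies: near-duplicate copies of chosen progenitors (never the reference)
    progenitors = rng.choice(np.arange(1, n_base), size=config.n_subfamilies, replace=False)
    copies = []
    for p in progenitors:
        for _ in range(config.subfamily_size - 1):
            row = base[p].copy()
            mut = rng.random(L) < config.subfamily_mutation_rate
            sub = rng.integers(0, N_AA - 1, size=L)
            sub = sub + (sub >= row)
            row = np.where(mut, sub, row).astype(np.int8)
            copies.append(row)
    matrix = np.vstack([base] + copies) if copies else base

    # gaps everywhere except the reference row
    gap_mask = rng.random(matrix.shape) < config.gap_rate
    gap_mask[0, :] = False

    ids = ["ref"] + [f"s{k:04d}" for k in range(1, matrix.shape[0])]
    rows = []
    for r in range(matrix.shape[0]):
        chars = [AMINO_ACIDS[int(a)] for a in matrix[r]]
        rows.append("".join("-" if gap_mask[r, c] else chars[c] for c in range(L)))
    msa = Msa(ids=ids, rows=rows, reference_id="ref")
    return msa, _build_blob_layout(config)


def _pack_blob(n: int, rng: np.random.Generator) -> np.ndarray:
    """Place n residue centers in a ball so all pairwise atom distances stay
    below 5 Å; rejection sampling with a minimum separation."""
    if n > 100:  # conservative random-packing capacity of the blob ball
        raise GenerationError(
            f"cannot pack {n} residues within a mutual 5 Å blob "
            f"(radius {_BLOB_RADIUS} Å, min separation {_MIN_SEP} Å)"
        )
    centers: list = []
    attempts = 0
    limit = 4000 * max(n, 1)
    while len(centers) < n:
        attempts += 1
        if attempts > limit:
            raise GenerationError(
                f"cannot pack {n} residues within a mutual 5 Å blob "
                f"(radius {_BLOB_RADIUS} Å, min separation {_MIN_SEP} Å)"
            )
        v = rng.uniform(-_BLOB_RADIUS, _BLOB_RADIUS, size=3)
        if np.linalg.norm(v) > _BLOB_RADIUS:
            continue
        if centers and np.min(np.linalg.norm(np.array(centers) - v, axis=1)) < _MIN_SEP:
            continue
        centers.append(v)
    return np.array(centers)


def generate_structure(
    ground_truth: GroundTruth,
    blob_spacing: float = 12.0,
    seed: int = 0,
    residue_names: dict | None = None,
) -> StructureModel:
    """Realize the blob layout as heavy-atom coordinates.

    Each residue gets a pseudo-center plus two satellite heavy atoms.
    Blobs sit on a line far enough apart that all non-designed inter-blob
    residue pairs are >= ``blob_spacing`` Å apart; designed contact pairs
    receive bridging atoms < 5 Å apart near the blob midpoint.  The
    realized geometry is verified exhaustively before returning.
    """
    if blob_spacing <= 5.0:
        raise ConfigurationError("blob_spacing must exceed the 5 Å contact cutoff")
    rng = np.random.default_rng(seed)
    blobs = ground_truth.blob_members()
    reach = _BLOB_RADIUS + _SATELLITE
    spacing_x = 2 * blob_spacing + 2 * reach + 4.0

    coords: dict[int, list] = {}
    blob_center: dict[int, np.ndarray] = {}
    for bid in sorted(blobs):
        members = sorted(blobs[bid])
        center = np.array([bid * spacing_x, 0.0, 0.0])
        blob_center[bid] = center
        local = _pack_blob(len(members), rng)
        for k, pos in enumerate(members):
            atoms = [center + local[k]]
            for _ in range(2):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                atoms.append(atoms[0] + direction * rng.uniform(0.2, _SATELLITE))
            coords[pos] = atoms

    for idx, (a, b) in enumerate(sorted(ground_truth.designed_contacts)):
        ba, bb = ground_truth.blob_assignment[a], ground_truth.blob_assignment[b]
        mid = (blob_center[ba] + blob_center[bb]) / 2.0
        offset = np.array([0.0, 2.0 * idx, 0.0])  # separate parallel bridges
        coords[a].append(mid + offset + np.array([-0.8, 0.0, 0.0]))
        coords[b].append(mid + offset + np.array([0.8, 0.0, 0.0]))

    model = StructureModel(
        coordinates={p: np.vstack(v) for p, v in coords.items()},
        chain_id="A",
        residue_names=residue_names or {p: "ALA" for p in coords},
    )
    _verify_geometry(model, ground_truth, blob_spacing)
    return model


def _verify_geometry(model: StructureModel, gt: GroundTruth, blob_spacing: float) -> None:
    from .networks import residue_min_distance

    residues = model.residues
    contacts = {frozenset(p) for p in gt.designed_contacts}
    for i, ra in enumerate(residues):
        for rb in residues[i + 1 :]:
            d = residue_min_distance(model.coordinates[ra], model.coordinates[rb])
            same = gt.blob_assignment[ra] == gt.blob_assignment[rb]
            if same or frozenset((ra, rb)) in contacts:
                if d >= 5.0:
                    raise GenerationError(
                        f"residues {ra},{rb} should be in contact but are {d:.2f} Å apart"
                    )
            elif d < blob_spacing:
                raise GenerationError(
                    f"residues {ra},{rb} from different blobs are only {d:.2f} Å apart"
                )


def generate_annotations(
    ground_truth: GroundTruth,
    target_odds_ratio: float,
    seed: int = 0,
    msa: Msa | None = None,
    n_placements: int = 200,
    features: tuple = ("BINDING", "METAL", "SITE", "MUTAGEN", "MOD_RES"),
    annotate_fraction: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place feature labels at a controlled odds ratio and emit annotation
    tables.

    Returns ``(catalytic_df, features_df)``: the catalytic-position table
    (position, residue_name) and the per-sequence feature table
    (sequence_id, position, feature).  Placement probability inside
    planted groups is ``target_odds_ratio`` times the background
    probability, scaled so the expected number of placed positions equals
    ``n_placements`` overall.  ACT_SITE is emitted at the planted
    catalytic positions.  ``ground_truth.feature_placements`` is updated.
    """
    if target_odds_ratio < 0:
        raise ConfigurationError("target_odds_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    positions = np.array(sorted(ground_truth.blob_assignment))
    in_group = np.isin(positions, sorted(set().union(*ground_truth.coupled_groups)))
    n_in, n_out = int(in_group.sum()), int((~in_group).sum())

    per_feature = n_placements / max(len(features), 1)
    p_out = per_feature / (n_in * target_odds_ratio + n_out)
    p_in = min(target_odds_ratio * p_out, 1.0)
    p_out = min(p_out, 1.0)

    placements: dict[str, frozenset] = {}
    for feat in features:
        probs = np.where(in_group, p_in, p_out)
        placed = positions[rng.random(positions.size) < probs]
        placements[feat] = frozenset(int(p) for p in placed)
    placements["ACT_SITE"] = frozenset(ground_truth.catalytic_positions)
    ground_truth.feature_placements = placements

    ref_residue: dict[int, str] = {}
    if msa is not None:
        ref_row = msa.reference_row
        pos = 0
        for ch in ref_row:
            if ch not in "-.":
                pos += 1
                ref_residue[pos] = ch.upper()
    catalytic_df = pd.DataFrame(
        {
            "position": sorted(ground_truth.catalytic_positions),
            "residue_name": [
                THREE_LETTER.get(ref_residue.get(p, "A"), "ALA")
                for p in sorted(ground_truth.catalytic_positions)
            ],
        }
    )

    rows = []
    if msa is not None:
        for sid, row in zip(msa.ids, msa.rows):
            # map reference position -> this sequence's local ungapped position;
            # synthetic alignments carry no reference gaps, so columns align 1:1
            local = 0
            local_at: dict[int, int] = {}
            for c, ch in enumerate(row):
                if ch not in "-.":
                    local += 1
                    local_at[c + 1] = local
            for feat in sorted(placements):
                for p in sorted(placements[feat]):
                    if p not in local_at:
                        continue
                    if rng.random() < annotate_fraction:
                        rows.append((sid, local_at[p], feat))
    features_df = pd.DataFrame(rows, columns=["sequence_id", "position", "feature"])
    return catalytic_df, features_df


def write_msa_fasta(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def write_structure_pdb(model: StructureModel, path) -> None:
    """Write the point-cloud chain as single-chain ATOM records."""
    from Bio.PDB import PDBIO, StructureBuilder

    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("synthetic")
    sb.init_model(0)
    sb.init_chain(model.chain_id)
    sb.init_seg("    ")
    for pos in model.residues:
        sb.init_residue(model.residue_names.get(pos, "ALA"), " ", int(pos), " ")
        for k, xyz in enumerate(model.coordinates[pos]):
            name = f"C{k + 1}"
            sb.init_atom(name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ", name, element="C")
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def write_catalytic_tsv(catalytic_df: pd.DataFrame, path) -> None:
    catalytic_df.to_csv(path, sep="\t", index=False)


def read_catalytic_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "position" not in df.columns:
        raise ValueError("catalytic TSV needs a 'position' column")
    return df


def generate_cluster_network_ensemble(
    n_families: int, seed: int = 0
) -> list[tuple[ClusterNetwork3D, dict]]:
    """Labelled 3DCN ensemble in the separable signal regime.

    Each family has one catalytic cluster built to be larger, of higher
    degree and more central (a hub) than its non-catalytic neighbours —
    the regime where topology-based prediction is expected to work.
    Returns ``[(cluster_network, {cluster_id: is_catalytic}), ...]``.
    """
    import networkx as nx

    out = []
    seeds = np.random.SeedSequence(seed).spawn(n_families)
    for fam, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        n_noncat = int(rng.integers(4, 8))
        sizes = [int(rng.integers(16, 25))] + [int(rng.integers(4, 9)) for _ in range(n_noncat)]
        clusters = {}
        next_res = 1
        for k, size in enumerate(sizes):
            cid = f"{k}.0"
            clusters[cid] = Mi3dCluster(
                cluster_id=cid,
                parent_mi_cluster=k,
                residues=frozenset(range(next_res, next_res + size)),
                catalytic=(k == 0),
            )
            next_res += size
        g = nx.Graph()
        g.add_nodes_from(clusters)
        hub = "0.0"
        for k in range(1, len(sizes)):
            g.add_edge(hub, f"{k}.0")
        # sparse peripheral edges keep non-catalytic degrees low but nonzero
        for a in range(1, len(sizes)):
            for b in range(a + 1, len(sizes)):
                if rng.random() < 0.15:
                    g.add_edge(f"{a}.0", f"{b}.0")
        cn = ClusterNetwork3D(graph=g, clusters=clusters)
        truth = {cid: c.catalytic for cid, c in clusters.items()}
        out.append((cn, truth))
    return out
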