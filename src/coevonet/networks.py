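"""Residue networks: the mutual-information network (MIN) and the distance
network (DN).

Both are undirected simple graphs over 1-based reference residue positions.
MIN edges connect column pairs whose co-evolution z-score reaches the
threshold (inclusive, default 6.0).  DN edges connect residues whose
minimum heavy-atom distance is strictly below the cutoff (default 5 Å,
the approximate upper limit for attractive van der Waals contacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError
from .mi import MiMatrix

logger = logging.getLogger(__name__)

DISTANCE_CUTOFF = 5.0
Z_THRESHOLD = 6.0
_HYDROGEN = {"H", "D"}


@dataclass
class StructureModel:
    """Heavy-atom coordinates per residue of a single chain."""

    coordinates: dict[int, np.ndarray]  # residue position -> (n_atoms, 3) Å
    chain_id: str = "A"
    residue_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, xyz in self.coordinates.items():
            xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
            if xyz.shape[0] == 0 or not np.isfinite(xyz).all():
                raise ValueError(f"residue {pos}: needs >=1 finite heavy atom")
            self.coordinates[pos] = xyz

    @property
    def residues(self) -> list[int]:
        return sorted(self.coordinates)


@dataclass
class ResidueNetwork:
    """An undirected simple graph over residue positions, tagged by origin."""

    graph: nx.Graph
    kind: str  # "MIN" | "DN" | derived
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


def read_pdb(path, chain_id: str | None = None) -> StructureModel:
    """Read heavy-atom coordinates from ATOM records of a PDB file.

    HETATM records and waters are ignored; hydrogens/deuteriums are
    excluded; for altloc duplicates the highest-occupancy atom wins (first
    on ties).  With ``chain_id=None`` the first chain of the first model is
    used.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    model = next(structure.get_models(), None)
    if model is None:
        raise FormatError(f"no model in {path}")
    chains = list(model.get_chains())
    if not chains:
        raise FormatError(f"no chain in {path}")
    if chain_id is None:
        chain = chains[0]
    else:
        match = [c for c in chains if c.id == chain_id]
        if not match:
            raise KeyError(f"chain {chain_id!r} not in {path}")
        chain = match[0]

    coords: dict[int, list[np.ndarray]] = {}
    names: dict[int, str] = {}
    for residue in chain:
        hetflag, resseq, _ = residue.id
        if hetflag.strip():  # HETATM / water
            continue
        best: dict[str, tuple[float, np.ndarray]] = {}
        for atom in residue:
            element = (atom.element or "").strip().upper()
            if element in _HYDROGEN:
                continue
            occ = atom.get_occupancy()
            occ = 1.0 if occ is None else float(occ)
            key = atom.get_name()
            if key not in best or occ > best[key][0]:
                best[key] = (occ, np.asarray(atom.coord, dtype=float))
        if best:
            coords[int(resseq)] = [xyz for _, xyz in best.values()]
            names[int(resseq)] = residue.get_resname()
    if not coords:
        raise FormatError(f"no heavy atoms found in {path}")
    return StructureModel(
        coordinates={p: np.vstack(v) for p, v in coords.items()},
        chain_id=chain.id,
        residue_names=names,
    )


def build_min(mi: MiMatrix, threshold: float = Z_THRESHOLD) -> ResidueNetwork:
    """MIN: edge where z >= threshold; every scored column is a node."""
    g = nx.Graph()
    g.add_nodes_from(mi.ref_positions)
    L = mi.n_columns
    for i in range(L):
        for j in range(i + 1, L):
            if mi.missing[i, j]:
                continue
            if mi.z[i, j] >= threshold:
                g.add_edge(mi.ref_positions[i], mi.ref_positions[j])
    return ResidueNetwork(graph=g, kind="MIN", provenance={"z_threshold": threshold})


def residue_min_distance(atoms_a: np.ndarray, atoms_b: np.ndarray) -> float:
    """Minimum Euclidean distance over the heavy-atom cross product."""
    a = np.atleast_2d(np.asarray(atoms_a, dtype=float))
    b = np.atleast_2d(np.asarray(atoms_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("residues must each have at least one heavy atom")
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def build_dn(structure: StructureModel, cutoff: float = DISTANCE_CUTOFF) -> ResidueNetwork:
    """DN: edge where the minimum heavy-atom distance is strictly < cutoff."""
    residues = structure.residues
    if len(residues) < 2:
        raise ValueError("need at least 2 residues to build a distance network")
    atoms = np.vstack([structure.coordinates[r] for r in residues])
    owner = np.concatenate(
        [np.full(len(structure.coordinates[r]), k) for k, r in enumerate(residues)]
    )
    tree = cKDTree(atoms)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(residues)
    if len(pairs):
        d = np.linalg.norm(atoms[pairs[:, 0]] - atoms[pairs[:, 1]], axis=1)
        strict = pairs[d < cutoff]  # query_pairs is inclusive; the edge rule is not
        for ia, ib in strict:
            ra, rb = residues[owner[ia]], residues[owner[ib]]
            if ra != rb:
                g.add_edge(ra, rb)
    return ResidueNetwork(graph=g, kind="DN", provenance={"cutoff": cutoff})


def giant_component(net: ResidueNetwork) -> ResidueNetwork:
    """Induced subgraph on the largest component; ties -> smallest min node id."""
    if net.graph.number_of_nodes() == 0:
        return ResidueNetwork(graph=nx.Graph(), kind=net.kind, provenance=dict(net.provenance))
    comps = list(nx.connected_components(net.graph))
    comps.sort(key=lambda c: (-len(c), min(c)))
    sub = net.graph.subgraph(comps[0]).copy()
    prov = dict(net.provenance)
    prov["giant_component_of"] = net.graph.number_of_nodes()
    return ResidueNetwork(graph=sub, kind=net.kind, provenance=prov)


def write_edge_list_tsv(net: ResidueNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_edge_list_tsv(path, kind: str = "generic") -> ResidueNetwork:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node_a"):
            raise FormatError(f"unexpected edge-list header in {path}")
        for line in fh:
            a, b = line.split()[:2]
            g.add_edge(int(a), int(b))
    return ResidueNetwork(graph=g, kind=kind, provenance={"source": str(path)})
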