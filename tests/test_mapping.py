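"""Structural mapping: MI3D clusters, catalytic labels, 3DCN, inter-cluster z."""

import itertools

import networkx as nx
import numpy as np
import pytest

from coevonet import (
    MiMatrix,
    Mi3dCluster,
    StructureModel,
    build_3dcn,
    build_dn,
    inter_cluster_coevolution_z,
    label_catalytic,
    map_to_structure,
)
from coevonet.networks import ResidueNetwork

from helpers import bfs_components


def _dn(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return ResidueNetwork(graph=g, kind="DN")


class TestMapToStructure:
    def test_clique_cluster_maps_to_itself(self):
        dn = _dn(itertools.combinations(range(1, 6), 2))
        out = map_to_structure({1, 2, 3, 4, 5}, dn, parent_id=3)
        assert len(out) == 1
        assert out[0].residues == frozenset({1, 2, 3, 4, 5})
        assert out[0].parent_mi_cluster == 3
        assert out[0].cluster_id == "3.0"

    def test_non_contacting_residues_all_dropped(self):
        dn = _dn([], nodes=range(1, 6))
        assert map_to_structure({1, 2, 3, 4, 5}, dn) == []

    def test_two_blobs_give_two_clusters(self):
        blob_a = list(itertools.combinations([1, 2, 3, 4], 2))
        blob_b = list(itertools.combinations([10, 11, 12, 13], 2))
        dn = _dn(blob_a + blob_b)
        out = map_to_structure({1, 2, 3, 4, 10, 11, 12, 13}, dn, parent_id=0)
        assert [sorted(c.residues) for c in out] == [[1, 2, 3, 4], [10, 11, 12, 13]]

    def test_matches_bfs_component_oracle_on_random_clusters(self, rng):
        for _ in range(30):
            g = nx.erdos_renyi_graph(25, 0.12, seed=int(rng.integers(1e6)))
            dn = ResidueNetwork(graph=g, kind="DN")
            cluster = set(rng.choice(25, size=12, replace=False).tolist())
            out = map_to_structure(cluster, dn, min_size=4)
            sub_edges = [(a, b) for a, b in g.edges() if a in cluster and b in cluster]
            expected = {
                frozenset(c)
                for c in bfs_components(sorted(cluster & set(g.nodes)), sub_edges)
                if len(c) >= 4
            }
            assert {c.residues for c in out} == expected

    def test_same_parent_components_are_dn_disconnected(self):
        dn = _dn(
            list(itertools.combinations([1, 2, 3, 4], 2))
            + list(itertools.combinations([7, 8, 9, 10], 2))
        )
        out = map_to_structure({1, 2, 3, 4, 7, 8, 9, 10}, dn)
        for a, b in itertools.combinations(out, 2):
            for ra in a.residues:
                for rb in b.residues:
                    assert not dn.graph.has_edge(ra, rb)


def _line_structure(positions_x: dict) -> StructureModel:
    return StructureModel(
        coordinates={p: np.array([[x, 0.0, 0.0]]) for p, x in positions_x.items()}
    )


class TestLabelCatalytic:
    def _cluster(self, residues):
        return Mi3dCluster(cluster_id="0.0", parent_mi_cluster=0, residues=frozenset(residues))

    def test_cluster_containing_catalytic_residue(self):
        model = _line_structure({1: 0.0, 2: 1.0, 3: 2.0, 9: 50.0})
        out = label_catalytic(self._cluster({1, 2, 3}), {2}, model)
        assert out.catalytic is True

    def test_five_angstrom_boundary_is_strict(self):
        model = _line_structure({1: 0.0, 2: 1.0, 9: 6.0})  # residue 2 -> 9: 5.0 Å
        out = label_catalytic(self._cluster({1, 2}), {9}, model)
        assert out.catalytic is False

    def test_nearby_external_catalytic_residue(self):
        model = _line_structure({1: 0.0, 2: 1.0, 9: 5.2})  # residue 2 -> 9: 4.2 Å
        out = label_catalytic(self._cluster({1, 2}), {9}, model)
        assert out.catalytic is True

    def test_empty_catalytic_list_flags_non_catalytic(self):
        model = _line_structure({1: 0.0, 2: 1.0})
        out = label_catalytic(self._cluster({1, 2}), set(), model)
        assert out.catalytic is False

    def test_every_cluster_gets_exactly_one_flag(self, small_family):
        truth, structure = small_family["truth"], small_family["structure"]
        dn = build_dn(structure)
        flags = []
        for k, group in enumerate(truth.coupled_groups):
            for c in map_to_structure(group, dn, parent_id=k):
                out = label_catalytic(c, truth.catalytic_positions, structure)
                assert out.catalytic in (True, False)
                flags.append(out)
        # only the planted catalytic group's cluster is catalytic
        catalytic_parents = {c.parent_mi_cluster for c in flags if c.catalytic}
        assert catalytic_parents == {0}


class TestBuild3dcn:
    def test_separate_blobs_have_no_edges(self):
        model = _line_structure({1: 0.0, 2: 1.0, 3: 2.0, 11: 50.0, 12: 51.0, 13: 52.0})
        a = Mi3dCluster("0.0", 0, frozenset({1, 2, 3}))
        b = Mi3dCluster("1.0", 1, frozenset({11, 12, 13}))
        cn = build_3dcn([a, b], model)
        assert cn.graph.number_of_edges() == 0

    def test_single_contact_pair_creates_edge(self, small_family):
        truth, structure = small_family["truth"], small_family["structure"]
        clusters = [
            Mi3dCluster(f"{k}.0", k, frozenset(group))
            for k, group in enumerate(truth.coupled_groups)
        ]
        cn = build_3dcn(clusters, structure)
        # the generator bridges the catalytic group (parent 0) to both others
        assert set(map(tuple, map(sorted, cn.graph.edges))) == {("0.0", "1.0")}

    def test_matches_exhaustive_contact_scan(self, rng):
        coords = {i: rng.normal(scale=6.0, size=(2, 3)) for i in range(1, 17)}
        model = StructureModel(coordinates=dict(coords))
        clusters = [
            Mi3dCluster(f"{k}.0", k, frozenset(range(4 * k + 1, 4 * k + 5)))
            for k in range(4)
        ]
        cn = build_3dcn(clusters, model)
        from coevonet import residue_min_distance

        expected = set()
        for a, b in itertools.combinations(clusters, 2):
            if any(
                residue_min_distance(coords[ra], coords[rb]) < 5.0
                for ra in a.residues for rb in b.residues
            ):
                expected.add(tuple(sorted((a.cluster_id, b.cluster_id))))
        assert set(map(tuple, map(sorted, cn.graph.edges))) == expected


def _z_matrix(L, hot_pairs, base=0.0, hot=10.0):
    z = np.full((L, L), base)
    for i, j in hot_pairs:
        z[i, j] = z[j, i] = hot
    missing = np.eye(L, dtype=bool)
    nan = np.full((L, L), np.nan)
    return MiMatrix(
        ref_positions=list(range(1, L + 1)),
        mi=nan, apc=nan, mip=nan, z=z, missing=missing, lam=0.05, n_perm=10,
    )


class TestInterClusterCoevolutionZ:
    def test_observed_fraction_extremes(self):
        a = Mi3dCluster("0.0", 0, frozenset({1, 2}))
        b = Mi3dCluster("1.0", 1, frozenset({3, 4}))
        cold = _z_matrix(6, [])
        obs, _ = inter_cluster_coevolution_z(a, b, cold, n_random=50, seed=1)
        assert obs == 0.0
        hot = _z_matrix(6, [(i, j) for i in range(6) for j in range(6) if i != j])
        obs, _ = inter_cluster_coevolution_z(a, b, hot, n_random=50, seed=1)
        assert obs == 1.0

    def test_null_mean_matches_exhaustive_enumeration(self):
        # 8-residue protein, hot pairs between {1,2,3} and {6,7,8}
        hot_pairs = [(0, 5), (1, 6), (2, 7), (0, 6)]
        mm = _z_matrix(8, hot_pairs)
        a = Mi3dCluster("0.0", 0, frozenset({1, 2, 3}))
        b = Mi3dCluster("1.0", 1, frozenset({6, 7, 8}))
        # exhaustive: all ordered disjoint (A', B') subset pairs of sizes 3,3
        positions = list(range(1, 9))
        fractions = []
        for aa in itertools.combinations(positions, 3):
            rest = [p for p in positions if p not in aa]
            for bb in itertools.combinations(rest, 3):
                hits = sum(
                    1 for ra in aa for rb in bb
                    if mm.z_between(ra, rb) >= 6.0
                )
                fractions.append(hits / 9)
        exhaustive_mean = np.mean(fractions)
        obs, z = inter_cluster_coevolution_z(a, b, mm, n_random=4000, seed=3)
        # reconstruct the Monte-Carlo null mean from the z-score using the
        # enumeration sd (the MC sd converges to it); compare to enumeration
        rng_null_mean = obs - z * np.std(fractions)
        assert abs(rng_null_mean - exhaustive_mean) < 0.02

    def test_deterministic_given_seed(self):
        mm = _z_matrix(10, [(0, 5), (2, 7)])
        a = Mi3dCluster("0.0", 0, frozenset({1, 2, 3}))
        b = Mi3dCluster("1.0", 1, frozenset({6, 7, 8}))
        r1 = inter_cluster_coevolution_z(a, b, mm, n_random=200, seed=11)
        r2 = inter_cluster_coevolution_z(a, b, mm, n_random=200, seed=11)
        assert r1 == r2
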