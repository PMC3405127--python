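"""The synthetic family generator: planted coupling, geometry, annotations."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coevonet import (
    GroundTruth,
    PlantedGroup,
    SyntheticConfig,
    build_dn,
    generate_annotations,
    generate_cluster_network_ensemble,
    generate_msa,
    generate_structure,
    residue_min_distance,
)
from coevonet.errors import ConfigurationError, GenerationError
from coevonet.synthetic import read_catalytic_tsv, write_catalytic_tsv, write_msa_fasta

from conftest import small_config


class TestGenerateMsa:
    def test_same_seed_reproduces_byte_identical_alignment(self):
        cfg = small_config(seed=5)
        a, _ = generate_msa(cfg)
        b, _ = generate_msa(small_config(seed=5))
        assert a.ids == b.ids and a.rows == b.rows

    def test_different_seed_differs(self):
        a, _ = generate_msa(small_config(seed=5))
        b, _ = generate_msa(small_config(seed=6))
        assert a.rows != b.rows

    def test_noise_free_group_is_function_of_latent_state(self):
        cfg = SyntheticConfig(
            n_sequences=80,
            n_columns=12,
            planted_groups=(PlantedGroup(columns=(0, 1, 2, 3), n_states=2, noise=0.0),),
            gap_rate=0.0,
            n_subfamilies=1,
            subfamily_size=1,
            seed=3,
        )
        msa, _ = generate_msa(cfg)
        patterns = {row[:4] for row in msa.rows}
        assert len(patterns) == 2  # one pattern per latent state

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(
                planted_groups=(PlantedGroup(columns=(0, 1, 60)),), n_columns=50
            ).validate()
        with pytest.raises(ConfigurationError):
            SyntheticConfig(
                planted_groups=(
                    PlantedGroup(columns=(0, 1)),
                    PlantedGroup(columns=(1, 2)),
                )
            ).validate()
        with pytest.raises(ConfigurationError):
            SyntheticConfig(
                planted_groups=(PlantedGroup(columns=(0, 1), noise=0.6),)
            ).validate()

    def test_reference_row_is_gap_free(self):
        msa, _ = generate_msa(small_config(seed=9, gap_rate=0.2))
        assert "-" not in msa.rows[msa.reference_index]

    def test_ground_truth_manifest_invariants(self):
        _, gt = generate_msa(small_config(seed=2))
        gt.validate()
        # catalytic positions live in exactly one blob
        blobs = {gt.blob_assignment[p] for p in gt.catalytic_positions}
        assert len(blobs) == 1 and blobs == {gt.catalytic_blob}
        # every planted column has a structural residue
        for group in gt.coupled_groups:
            assert group <= set(gt.blob_assignment)


class TestGenerateStructure:
    def test_blob_members_mutually_within_five_angstroms(self):
        gt = GroundTruth(
            coupled_groups=[frozenset(range(1, 13))],
            blob_assignment={p: 0 for p in range(1, 13)},
            catalytic_positions=frozenset({2, 3}),
        )
        model = generate_structure(gt, seed=1)
        pairs = list(itertools.combinations(range(1, 13), 2))
        assert len(pairs) == 66
        for a, b in pairs:
            d = residue_min_distance(model.coordinates[a], model.coordinates[b])
            assert d < 5.0

    def test_two_blobs_without_contacts_give_two_dn_components(self):
        gt = GroundTruth(
            coupled_groups=[frozenset({1, 2, 3, 4})],
            blob_assignment={1: 0, 2: 0, 3: 0, 4: 0, 5: 1, 6: 1, 7: 1, 8: 1},
            catalytic_positions=frozenset({2}),
        )
        dn = build_dn(generate_structure(gt, seed=4))
        assert nx.number_connected_components(dn.graph) == 2

    def test_single_blob_of_four_is_complete(self):
        gt = GroundTruth(
            coupled_groups=[frozenset({1, 2, 3, 4})],
            blob_assignment={1: 0, 2: 0, 3: 0, 4: 0},
            catalytic_positions=frozenset({2}),
        )
        dn = build_dn(generate_structure(gt, seed=2))
        assert dn.number_of_edges() == 6

    def test_designed_contact_bridges_blobs(self):
        gt = GroundTruth(
            coupled_groups=[frozenset({1, 2, 3, 4})],
            blob_assignment={1: 0, 2: 0, 3: 0, 4: 0, 5: 1, 6: 1, 7: 1, 8: 1},
            catalytic_positions=frozenset({2}),
            designed_contacts=frozenset({(4, 5)}),
        )
        model = generate_structure(gt, blob_spacing=12.0, seed=4)
        dn = build_dn(model)
        assert dn.graph.has_edge(4, 5)
        # non-designed inter-blob pairs stay >= blob_spacing apart
        for a in (1, 2, 3):
            for b in (6, 7, 8):
                d = residue_min_distance(model.coordinates[a], model.coordinates[b])
                assert d >= 12.0

    def test_overfull_blob_raises_generation_error(self):
        n = 150
        gt = GroundTruth(
            coupled_groups=[frozenset(range(1, n + 1))],
            blob_assignment={p: 0 for p in range(1, n + 1)},
            catalytic_positions=frozenset({2}),
        )
        with pytest.raises(GenerationError):
            generate_structure(gt, seed=1)

    def test_blob_spacing_must_exceed_cutoff(self):
        gt = GroundTruth(
            coupled_groups=[frozenset({1, 2, 3, 4})],
            blob_assignment={1: 0, 2: 0, 3: 0, 4: 0},
            catalytic_positions=frozenset({2}),
        )
        with pytest.raises(ConfigurationError):
            generate_structure(gt, blob_spacing=4.0)

    def test_deterministic_given_seed(self):
        _, gt = generate_msa(small_config(seed=8))
        a = generate_structure(gt, seed=5)
        b = generate_structure(gt, seed=5)
        for p in a.residues:
            assert np.array_equal(a.coordinates[p], b.coordinates[p])


class TestGenerateAnnotations:
    def _family(self, seed=6):
        return generate_msa(small_config(seed=seed))

    def test_odds_ratio_zero_places_nothing_in_groups(self):
        msa, gt = self._family()
        generate_annotations(gt, target_odds_ratio=0.0, seed=1, msa=msa)
        in_group = set().union(*gt.coupled_groups)
        for feat, positions in gt.feature_placements.items():
            if feat != "ACT_SITE":
                assert not positions & in_group

    def test_odds_ratio_one_is_neutral(self):
        # empirical OR inside vs outside planted groups near 1 at n=200
        ors = []
        for seed in range(6):
            msa, gt = self._family(seed=20 + seed)
            generate_annotations(gt, 1.0, seed=seed, msa=msa, n_placements=200)
            in_group = set().union(*gt.coupled_groups)
            all_pos = set(gt.blob_assignment)
            placed = set()
            for feat, positions in gt.feature_placements.items():
                if feat != "ACT_SITE":
                    placed |= positions
            p_in = len(placed & in_group) / len(in_group)
            p_out = len(placed - in_group) / len(all_pos - in_group)
            if p_out > 0:
                ors.append(p_in / p_out)
        assert 0.7 < np.mean(ors) < 1.4

    def test_act_site_marks_catalytic_positions(self):
        msa, gt = self._family()
        catalytic_df, features_df = generate_annotations(gt, 2.0, seed=3, msa=msa)
        assert set(catalytic_df["position"]) == set(gt.catalytic_positions)
        assert gt.feature_placements["ACT_SITE"] == gt.catalytic_positions

    def test_catalytic_tsv_round_trip(self, tmp_path):
        msa, gt = self._family()
        catalytic_df, _ = generate_annotations(gt, 2.0, seed=3, msa=msa)
        path = tmp_path / "catalytic.tsv"
        write_catalytic_tsv(catalytic_df, path)
        loaded = read_catalytic_tsv(path)
        pd.testing.assert_frame_equal(loaded, catalytic_df)

    def test_deterministic_given_seed(self):
        msa, gt = self._family()
        a = generate_annotations(gt, 3.0, seed=11, msa=msa)
        msa2, gt2 = self._family()
        b = generate_annotations(gt2, 3.0, seed=11, msa=msa2)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestGroundTruthJson:
    def test_round_trip(self, tmp_path):
        msa, gt = generate_msa(small_config(seed=13))
        generate_annotations(gt, 2.5, seed=1, msa=msa)
        path = tmp_path / "gt.json"
        gt.to_json(path)
        loaded = GroundTruth.from_json(path)
        assert loaded.coupled_groups == gt.coupled_groups
        assert loaded.blob_assignment == gt.blob_assignment
        assert loaded.catalytic_positions == gt.catalytic_positions
        assert loaded.feature_placements == gt.feature_placements
        assert loaded.designed_contacts == gt.designed_contacts


class TestClusterNetworkEnsemble:
    def test_one_catalytic_cluster_per_family(self):
        for cn, truth in generate_cluster_network_ensemble(6, seed=2):
            assert sum(truth.values()) == 1
            assert set(truth) == set(cn.graph.nodes)

    def test_deterministic(self):
        a = generate_cluster_network_ensemble(4, seed=9)
        b = generate_cluster_network_ensemble(4, seed=9)
        for (cn_a, t_a), (cn_b, t_b) in zip(a, b):
            assert t_a == t_b
            assert set(cn_a.graph.edges) == set(cn_b.graph.edges)


def test_fasta_writer_round_trips_through_reader(tmp_path):
    from coevonet import read_msa

    msa, _ = generate_msa(small_config(seed=21))
    path = tmp_path / "fam.fasta"
    write_msa_fasta(msa, path)
    loaded = read_msa(path, "fasta", "ref")
    assert loaded.ids == msa.ids and loaded.rows == msa.rows
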