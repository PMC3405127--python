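"""Mutual information, APC correction and permutation z-scores."""

import numpy as np
import pytest

from coevonet import (
    Msa,
    apc_correct,
    cluster_weights,
    mi_score,
    pair_frequencies,
    permutation_zscores,
    trim_msa,
)
from coevonet.mi import _joint_counts, _mi_from_counts
from coevonet.alignment import encode_sequence

from helpers import brute_force_apc, brute_force_mi


def _prep(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    tmsa = trim_msa(Msa(ids=ids, rows=rows, reference_id=ids[0]))
    return tmsa, cluster_weights(tmsa)


class TestPairFrequencies:
    def test_all_same_residue_single_cell(self):
        tmsa, w = _prep(["AAWW", "AAWW", "AAWW", "AAWW"])
        joint, pi, pj = pair_frequencies(tmsa, w, 0, 1, lam=0.0)
        assert joint[0, 0] == pytest.approx(1.0)
        assert joint.sum() == pytest.approx(1.0)

    def test_pseudocount_only_limit_is_uniform(self):
        # complementary gap patterns: no sequence covers both columns
        from coevonet.alignment import SequenceWeights, TrimmedMsa

        tmsa = TrimmedMsa(
            ids=["a", "b"], rows=["A-", "-W"], reference_id="a",
            original_rows=["A-", "-W"], kept_columns=[0, 1],
            col_to_refpos={0: 1, 1: 2}, refpos_to_col={1: 0, 2: 1},
        )
        w = SequenceWeights(
            ids=["a", "b"], weights=np.array([1.0, 1.0]),
            threshold=0.62, cluster_ids=np.array([0, 1]),
        )
        joint, _, _ = pair_frequencies(tmsa, w, 0, 1, lam=0.05)
        assert np.allclose(joint, 1.0 / 400)

    def test_weighted_counts_match_hand_normalization(self):
        # sequences 0,1 identical -> weights 0.5/0.5; seq 2 weight 1
        tmsa, w = _prep(["ACDE", "ACDE", "WYDE"])
        assert np.allclose(sorted(w.weights), [0.5, 0.5, 1.0])
        joint, pi, pj = pair_frequencies(tmsa, w, 0, 1, lam=0.0)
        # weighted counts: (A,C) gets 1.0, (W,Y) gets 1.0 -> each 0.5
        a, c, wi, y = (encode_sequence(x)[0] for x in "ACWY")
        assert joint[a, c] == pytest.approx(0.5)
        assert joint[wi, y] == pytest.approx(0.5)
        assert pi[a] == pytest.approx(0.5)

    def test_vectorized_tensor_agrees_with_per_pair_path(self, small_family):
        tmsa, w = small_family["tmsa"], small_family["weights"]
        enc = tmsa.encoded()
        counts = _joint_counts(enc, w.weights)
        rng = np.random.default_rng(5)
        for _ in range(10):
            i, j = rng.choice(tmsa.n_columns, size=2, replace=False)
            joint, _, _ = pair_frequencies(tmsa, w, int(i), int(j), lam=0.05)
            ref = counts[i, :, j, :] + 0.05
            ref /= ref.sum()
            assert np.allclose(joint, ref, atol=1e-12)


class TestMiScore:
    def test_independent_columns_zero(self):
        pi = np.array([0.25, 0.75])
        pj = np.array([0.6, 0.4])
        joint = np.zeros((20, 20))
        joint[:2, :2] = np.outer(pi, pj)
        assert mi_score(joint) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_coupling_is_one_bit(self):
        joint = np.zeros((20, 20))
        joint[0, 0] = joint[1, 1] = 0.5
        assert mi_score(joint) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            t = rng.random((3, 3))
            t /= t.sum()
            joint = np.zeros((20, 20))
            joint[:3, :3] = t
            assert mi_score(joint) == pytest.approx(brute_force_mi(joint), abs=1e-12)

    def test_unnormalized_table_rejected(self):
        with pytest.raises(ValueError):
            mi_score(np.full((20, 20), 0.01))

    def test_mi_nonnegative_and_entropy_bounded(self, rng):
        # lambda=0 joint tables from random small alignments
        for _ in range(10):
            rows = ["".join(rng.choice(list("ACDE"), size=2)) for _ in range(30)]
            tmsa, w = _prep(rows)
            joint, pi, pj = pair_frequencies(tmsa, w, 0, 1, lam=0.0)
            mi = mi_score(joint)
            h = lambda p: -np.sum(p[p > 0] * np.log2(p[p > 0]))
            assert -1e-12 <= mi <= min(h(pi), h(pj)) + 1e-9


class TestApc:
    def test_worked_three_column_example(self):
        mi = np.array([[np.nan, 2.0, 4.0], [2.0, np.nan, 6.0], [4.0, 6.0, np.nan]])
        _, mip = apc_correct(mi)
        assert mip[1, 2] == pytest.approx(1.0)
        assert mip[0, 2] == pytest.approx(0.25)
        assert mip[0, 1] == pytest.approx(-1.0)

    def test_constant_matrix_corrects_to_zero(self):
        mi = np.full((5, 5), 3.7)
        np.fill_diagonal(mi, np.nan)
        _, mip = apc_correct(mi)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(mip[off], 0.0)

    def test_all_zero_mi_stays_zero(self):
        mi = np.zeros((4, 4))
        np.fill_diagonal(mi, np.nan)
        _, mip = apc_correct(mi)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(mip[off], 0.0)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            L = int(rng.integers(3, 21))
            sym = rng.random((L, L))
            sym = (sym + sym.T) / 2
            np.fill_diagonal(sym, np.nan)
            _, mip = apc_correct(sym)
            expected = brute_force_apc(np.nan_to_num(sym))
            off = ~np.eye(L, dtype=bool)
            assert np.allclose(mip[off], expected[off], atol=1e-12)


class TestPermutationZscores:
    def test_deterministic_under_seed(self):
        rows = ["ACDEAC", "ACDEAC", "CADECA", "CADECA", "ACDECA", "CADEAC"] * 10
        tmsa, w = _prep(rows)
        a = permutation_zscores(tmsa, w, n_perm=20, seed=9)
        b = permutation_zscores(tmsa, w, n_perm=20, seed=9)
        assert np.array_equal(a.z, b.z, equal_nan=True)

    def test_planted_pair_scores_high(self, small_family):
        mm, truth = small_family["mi"], small_family["truth"]
        group = sorted(truth.coupled_groups[0])
        z = [mm.z_between(a, b) for a in group for b in group if a < b]
        assert np.median(z) >= 6.0

    def test_alphabet_relabeling_leaves_z_invariant(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACDEFG"), size=8)) for _ in range(60)]
        tmsa, w = _prep(rows)
        mapping = dict(zip("ACDEFG", "KLMNPQ"))  # bijective recoding
        rows2 = ["".join(mapping[c] for c in r) for r in rows]
        tmsa2, w2 = _prep(rows2)
        a = permutation_zscores(tmsa, w, n_perm=30, seed=4)
        b = permutation_zscores(tmsa2, w2, n_perm=30, seed=4)
        assert np.allclose(a.z, b.z, equal_nan=True, atol=1e-9)

    def test_column_shuffling_destroys_planted_coupling(self, small_family):
        from scipy import stats

        cfg, truth = small_family["config"], small_family["truth"]
        tmsa = small_family["tmsa"]
        rng = np.random.default_rng(42)
        shuffled_rows = np.array([list(r) for r in tmsa.rows])
        for c in range(shuffled_rows.shape[1]):
            shuffled_rows[:, c] = shuffled_rows[rng.permutation(len(tmsa.rows)), c]
        rows = ["".join(r) for r in shuffled_rows]
        tmsa2, w2 = _prep(rows, ids=list(tmsa.ids))
        mm = permutation_zscores(tmsa2, w2, n_perm=60, seed=5)
        group_cols = [tmsa2.refpos_to_col[p] for p in sorted(truth.coupled_groups[0])]
        in_group = [
            mm.z[i, j]
            for i in group_cols for j in group_cols
            if i < j and np.isfinite(mm.z[i, j])
        ]
        background = [
            mm.z[i, j]
            for i in range(mm.n_columns) for j in range(i + 1, mm.n_columns)
            if i not in group_cols and j not in group_cols and np.isfinite(mm.z[i, j])
        ]
        # planted z under shuffled input is indistinguishable from background
        _, p = stats.ks_2samp(in_group, background)
        assert p > 0.01
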