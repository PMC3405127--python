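"""Weighted mutual information between alignment columns, with APC and
permutation z-scores.

For each pair of columns (i, j) the joint distribution of standard residues
is estimated from sequences carrying a residue at both columns, each
sequence contributing its redundancy weight, with a pseudocount ``lam``
added to every cell of the 20x20 table before normalization.  Raw MI (in
bits) is then background-corrected with the average product correction

    APC(i, j) = mean_MI(i, .) * mean_MI(j, .) / overall_mean_MI
    MIp(i, j) = MI(i, j) - APC(i, j)

and finally standardized against a null of alignments in which every
column has been shuffled independently across sequences:

    z(i, j) = (MIp_obs(i, j) - mean_perm(i, j)) / sd_perm(i, j)

The full MI + APC pipeline is recomputed for every shuffled replicate;
sequence weights are kept fixed (column shuffling preserves column
composition).  Column pairs with no usable sequence are scored "missing"
and excluded from APC means and from the downstream network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP_CODE, SequenceWeights, TrimmedMsa
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

N_AA = 20


@dataclass
class MiMatrix:
    """Symmetric per-column-pair co-evolution scores.

    Arrays are indexed by trimmed column; ``ref_positions`` carries the
    1-based reference residue position of each column.  Entries flagged in
    ``missing`` (and the diagonal) are undefined.
    """

    ref_positions: list[int]
    mi: np.ndarray
    apc: np.ndarray
    mip: np.ndarray
    z: np.ndarray
    missing: np.ndarray
    lam: float
    n_perm: int
    alphabet_size: int = N_AA
    seed: int | None = None
    _pos_index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._pos_index = {p: i for i, p in enumerate(self.ref_positions)}

    @property
    def n_columns(self) -> int:
        return len(self.ref_positions)

    def column_of(self, ref_position: int) -> int:
        return self._pos_index[ref_position]

    def z_between(self, ref_pos_a: int, ref_pos_b: int) -> float:
        """z-score between two reference positions; NaN if unscored."""
        ia = self._pos_index.get(ref_pos_a)
        ib = self._pos_index.get(ref_pos_b)
        if ia is None or ib is None or ia == ib or self.missing[ia, ib]:
            return float("nan")
        return float(self.z[ia, ib])


def _weighted_indicators(
    enc: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column one-hot stacks: weighted (L,20,n) and binary (L,20,n)."""
    n, L = enc.shape
    cols = enc.T  # (L, n)
    onehot = np.zeros((L, N_AA, n), dtype=float)
    l_idx, s_idx = np.nonzero(cols != GAP_CODE)
    onehot[l_idx, cols[l_idx, s_idx], s_idx] = 1.0
    weighted = onehot * weights[np.newaxis, np.newaxis, :]
    return weighted, onehot


def _joint_counts(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """All-pairs weighted joint count tensor, shape (L, 20, L, 20).

    counts[i, a, j, b] = sum of weights of sequences with residue a at
    column i and residue b at column j (sequences gapped at either column
    contribute nothing).
    """
    n, L = enc.shape
    weighted, onehot = _weighted_indicators(enc, weights)
    A = weighted.reshape(L * N_AA, n)
    B = onehot.reshape(L * N_AA, n)
    return (A @ B.T).reshape(L, N_AA, L, N_AA)


def _mi_from_counts(counts: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """(L, L) raw MI in bits and missing mask from the joint count tensor."""
    L = counts.shape[0]
    totals = counts.sum(axis=(1, 3))  # (L, L) usable weight per pair
    missing = totals <= 0.0
    joint = counts + lam  # pseudocount on every cell
    norm = joint.sum(axis=(1, 3), keepdims=True)
    p = joint / norm
    pi = p.sum(axis=3, keepdims=True)  # marginal of column i
    pj = p.sum(axis=1, keepdims=True)  # marginal of column j
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log2(p) - np.log2(pi) - np.log2(pj))
    terms = np.where(p > 0.0, terms, 0.0)
    mi = terms.sum(axis=(1, 3))
    np.fill_diagonal(mi, 0.0)
    np.fill_diagonal(missing, True)
    mi[missing] = np.nan
    return mi, missing


def pair_frequencies(
    tmsa: TrimmedMsa,
    weights: SequenceWeights,
    col_i: int,
    col_j: int,
    lam: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint 20x20 frequency table and marginals for one column pair.

    Straightforward per-sequence accumulation (the reference path for the
    vectorized all-pairs tensor used internally).  Raises
    :class:`DegenerateInputError` when no sequence carries a standard
    residue at both columns — such pairs are scored as missing.
    """
    if col_i == col_j:
        raise ValueError("col_i and col_j must differ")
    enc = tmsa.encoded()
    if not (0 <= col_i < enc.shape[1] and 0 <= col_j < enc.shape[1]):
        raise ValueError("column index out of range")
    counts = np.zeros((N_AA, N_AA), dtype=float)
    for s in range(enc.shape[0]):
        a, b = enc[s, col_i], enc[s, col_j]
        if a != GAP_CODE and b != GAP_CODE:
            counts[a, b] += weights.weights[s]
    if counts.sum() <= 0.0 and lam <= 0.0:
        raise DegenerateInputError(
            f"no usable sequence at column pair ({col_i}, {col_j})"
        )
    joint = counts + lam
    joint /= joint.sum()
    return joint, joint.sum(axis=1), joint.sum(axis=0)


def mi_score(joint: np.ndarray) -> float:
    """MI in bits of a normalized joint table; zero-probability terms drop out."""
    total = joint.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"joint table is not normalized (sum={total})")
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    mi = 0.0
    for a in range(joint.shape[0]):
        for b in range(joint.shape[1]):
            pab = joint[a, b]
            if pab > 0.0:
                mi += pab * math.log2(pab / (pi[a] * pj[b]))
    return mi


def apc_correct(
    mi: np.ndarray, missing: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Average product correction: returns (APC terms, MIp = MI - APC).

    Means run over scored (non-missing, off-diagonal) pairs only.  With an
    overall mean of zero the correction is defined as zero.
    """
    mi = np.asarray(mi, dtype=float)
    L = mi.shape[0]
    if missing is None:
        missing = np.isnan(mi)
        missing = missing | np.eye(L, dtype=bool)
    valid = ~missing
    np.fill_diagonal(valid, False)
    counts = valid.sum(axis=1)
    safe = np.where(valid, mi, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_means = np.where(counts > 0, safe.sum(axis=1) / np.maximum(counts, 1), 0.0)
    n_valid = valid.sum()
    overall = safe.sum() / n_valid if n_valid else 0.0
    if overall == 0.0:
        apc = np.zeros_like(mi)
    else:
        apc = np.outer(col_means, col_means) / overall
    mip = np.where(valid, mi - apc, np.nan)
    apc = np.where(valid, apc, np.nan)
    return apc, mip


def _mip_from_encoding(enc: np.ndarray, weights: np.ndarray, lam: float):
    counts = _joint_counts(enc, weights)
    mi, missing = _mi_from_counts(counts, lam)
    apc, mip = apc_correct(mi, missing)
    return mi, apc, mip, missing


def permutation_zscores(
    tmsa: TrimmedMsa,
    weights: SequenceWeights,
    lam: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> MiMatrix:
    """Full MI -> APC -> permutation z-score pipeline for all column pairs.

    Each replicate shuffles every column independently across sequences and
    recomputes MI and APC.  Pairs whose permutation sd is zero get z = +inf
    when the observed MIp exceeds the permutation mean, else 0.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    enc = tmsa.encoded()
    n, L = enc.shape
    w = np.asarray(weights.weights, dtype=float)
    mi, apc, mip, missing = _mip_from_encoding(enc, w, lam)

    rng = np.random.default_rng(seed)
    perm_sum = np.zeros((L, L))
    perm_sqsum = np.zeros((L, L))
    perm_n = np.zeros((L, L))
    for _ in range(n_perm):
        shuffled = np.empty_like(enc)
        for c in range(L):
            shuffled[:, c] = enc[rng.permutation(n), c]
        _, _, mip_r, missing_r = _mip_from_encoding(shuffled, w, lam)
        ok = ~missing_r
        perm_sum[ok] += mip_r[ok]
        perm_sqsum[ok] += mip_r[ok] ** 2
        perm_n[ok] += 1

    z = np.full((L, L), np.nan)
    scored = (~missing) & (perm_n >= 2)
    mean = np.where(perm_n > 0, perm_sum / np.maximum(perm_n, 1), 0.0)
    var = np.where(
        perm_n >= 2,
        (perm_sqsum - perm_n * mean**2) / np.maximum(perm_n - 1, 1),
        0.0,
    )
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z_val = (mip - mean) / sd
    zero_sd = scored & (sd <= 0.0)
    z[scored] = z_val[scored]
    if zero_sd.any():
        n_flag = int(zero_sd.sum()) // 2
        logger.warning("%d pairs had zero permutation sd; sentinel z applied", n_flag)
        z[zero_sd & (mip > mean)] = np.inf
        z[zero_sd & ~(mip > mean)] = 0.0
    missing_out = missing | (perm_n < 2)

    return MiMatrix(
        ref_positions=tmsa.reference_positions,
        mi=mi,
        apc=apc,
        mip=mip,
        z=z,
        missing=missing_out,
        lam=lam,
        n_perm=n_perm,
        seed=seed,
    )


def write_mi_tsv(mm: MiMatrix, path) -> None:
    """Pair table: col_i, col_j, ref_pos_i, ref_pos_j, MI, APC, MIp, z."""
    with open(path, "w") as fh:
        fh.write("col_i\tcol_j\tref_pos_i\tref_pos_j\tmi\tapc\tmip\tz\n")
        L = mm.n_columns
        for i in range(L):
            for j in range(i + 1, L):
                if mm.missing[i, j]:
                    continue
                fh.write(
                    f"{i}\t{j}\t{mm.ref_positions[i]}\t{mm.ref_positions[j]}\t"
                    f"{mm.mi[i, j]:.10g}\t{mm.apc[i, j]:.10g}\t"
                    f"{mm.mip[i, j]:.10g}\t{mm.z[i, j]:.10g}\n"
                )


def read_mi_tsv(path) -> MiMatrix:
    """Rebuild a :class:`MiMatrix` from the pair-table TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = sorted(set(df.col_i) | set(df.col_j))
    index = {c: k for k, c in enumerate(cols)}
    L = len(cols)
    refpos = [0] * L
    for _, r in df.iterrows():
        refpos[index[r.col_i]] = int(r.ref_pos_i)
        refpos[index[r.col_j]] = int(r.ref_pos_j)
    mats = {name: np.full((L, L), np.nan) for name in ("mi", "apc", "mip", "z")}
    missing = np.ones((L, L), dtype=bool)
    for _, r in df.iterrows():
        i, j = index[r.col_i], index[r.col_j]
        for name in mats:
            mats[name][i, j] = mats[name][j, i] = float(getattr(r, name))
        missing[i, j] = missing[j, i] = False
    return MiMatrix(
        ref_positions=refpos,
        mi=mats["mi"],
        apc=mats["apc"],
        mip=mats["mip"],
        z=mats["z"],
        missing=missing,
        lam=float("nan"),
        n_perm=0,
    )
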