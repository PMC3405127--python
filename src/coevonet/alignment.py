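"""Multiple sequence alignment handling: reading, trimming, identity weighting.

An alignment enters the pipeline as an :class:`Msa` (raw, possibly gappy),
is reduced to a :class:`TrimmedMsa` whose columns biject onto ungapped
positions of a designated reference sequence, and is finally given
per-sequence redundancy weights (:class:`SequenceWeights`) so that large
groups of near-identical sequences do not dominate column statistics.

Conventions
-----------
* Reference numbering is 1-based and equals the position in the ungapped
  reference sequence.
* The twenty standard amino acids are the working alphabet; gap characters
  (``-`` and ``.``) and ambiguity codes (B, Z, X, U, O, J) are treated as
  gaps everywhere downstream.
* Sequence identity is computed over columns where *both* sequences carry a
  standard residue; with no such column the identity is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: integer code used for anything that is not a standard amino acid
GAP_CODE = 20
_GAPLIKE = set("-.BZXUOJ*")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence as int8 codes (0-19 residues, 20 gap-like)."""
    out = np.full(len(seq), GAP_CODE, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = AA_INDEX.get(ch, GAP_CODE)
    return out


def is_residue(code_or_char) -> bool:
    if isinstance(code_or_char, str):
        return code_or_char.upper() in AA_INDEX
    return 0 <= int(code_or_char) < 20


@dataclass
class Msa:
    """A raw alignment: equal-length rows plus a designated reference row."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in length")
        if not self.rows:
            raise FormatError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.reference_id not in self.ids:
            raise KeyError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_index(self) -> int:
        return self.ids.index(self.reference_id)

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_index]


@dataclass
class TrimmedMsa:
    """Alignment after the trimming rules, with column <-> reference maps.

    ``rows`` hold only the kept columns of the kept sequences;
    ``original_rows`` retain the full-width rows of the kept sequences so
    that per-sequence (ungapped) coordinates can still be mapped to columns,
    e.g. when projecting sequence-local feature annotations.
    """

    ids: list[str]
    rows: list[str]
    reference_id: str
    original_rows: list[str]
    kept_columns: list[int]
    col_to_refpos: dict[int, int]
    refpos_to_col: dict[int, int]

    @property
    def n_columns(self) -> int:
        return len(self.kept_columns)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def reference_index(self) -> int:
        return self.ids.index(self.reference_id)

    @property
    def reference_positions(self) -> list[int]:
        return [self.col_to_refpos[c] for c in range(self.n_columns)]

    def encoded(self) -> np.ndarray:
        """(n_sequences, n_columns) int8 matrix of residue codes."""
        return np.vstack([encode_sequence(r) for r in self.rows])

    def sequence_position_to_column(self, seq_id: str) -> dict[int, int]:
        """Map 1-based ungapped positions of one kept sequence to trimmed columns."""
        row = self.original_rows[self.ids.index(seq_id)]
        kept = {c: k for k, c in enumerate(self.kept_columns)}
        out: dict[int, int] = {}
        pos = 0
        for c, ch in enumerate(row):
            if ch not in "-." :
                pos += 1
                if c in kept:
                    out[pos] = kept[c]
        return out

    def as_msa(self) -> Msa:
        return Msa(list(self.ids), list(self.rows), self.reference_id)


@dataclass
class SequenceWeights:
    """1/cluster-size redundancy weights at a fixed identity threshold."""

    ids: list[str]
    weights: np.ndarray
    threshold: float
    cluster_ids: np.ndarray = field(repr=False)

    @property
    def effective_sequences(self) -> float:
        return float(self.weights.sum())


def read_msa(path, fmt: str, reference_id: str) -> Msa:
    """Read an alignment in ``fasta`` or ``stockholm`` format.

    Raises :class:`FormatError` on empty/ragged input and :class:`KeyError`
    if the reference is absent.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq) for rec in aln]
    return Msa(ids=ids, rows=rows, reference_id=reference_id)


def trim_msa(msa: Msa) -> TrimmedMsa:
    """Apply the trimming rules and build the column <-> reference maps.

    Per pass: (1) drop columns gapped in the reference row; (2) drop columns
    with more than 50% gaps; (3) drop sequences covering less than 50% of the
    reference length.  Dropping sequences can change column gap fractions, so
    the pass is repeated until nothing changes; the result is therefore
    idempotent by construction.
    """
    n0 = msa.n_columns
    ref_idx = msa.reference_index
    enc = np.vstack([encode_sequence(r) for r in msa.rows])  # (n, C)
    keep_cols = np.arange(n0)
    keep_rows = np.arange(len(msa.rows))

    while True:
        sub = enc[np.ix_(keep_rows, keep_cols)]
        ref_row_pos = int(np.where(keep_rows == ref_idx)[0][0])
        # (1) columns gapped in the reference
        col_ok = sub[ref_row_pos] != GAP_CODE
        sub = sub[:, col_ok]
        keep_cols = keep_cols[col_ok]
        if sub.shape[1] == 0:
            raise DegenerateInputError("all columns removed during trimming")
        ref_len = sub.shape[1]  # ungapped reference length at this pass
        # (2) columns with >50% gaps (strict)
        gap_frac = (sub == GAP_CODE).mean(axis=0)
        col_ok2 = gap_frac <= 0.5
        sub = sub[:, col_ok2]
        keep_cols = keep_cols[col_ok2]
        if sub.shape[1] == 0:
            raise DegenerateInputError("all columns removed during trimming")
        # (3) sequences covering <50% of the reference length (strict)
        coverage = (sub != GAP_CODE).sum(axis=1) / ref_len
        row_ok = coverage >= 0.5
        row_ok[ref_row_pos] = True  # the reference always stays
        changed = (not col_ok.all()) or (not col_ok2.all()) or (not row_ok.all())
        keep_rows = keep_rows[row_ok]
        if not changed:
            break

    ids = [msa.ids[i] for i in keep_rows]
    original_rows = [msa.rows[i] for i in keep_rows]
    kept_columns = [int(c) for c in keep_cols]
    rows = ["".join(orig[c] for c in kept_columns) for orig in original_rows]

    # reference position = rank of the column among reference-residue columns
    ref_full = encode_sequence(msa.rows[ref_idx])
    refpos_of_col = np.cumsum(ref_full != GAP_CODE)  # 1-based at residue columns
    col_to_refpos = {k: int(refpos_of_col[c]) for k, c in enumerate(kept_columns)}
    refpos_to_col = {p: k for k, p in col_to_refpos.items()}
    return TrimmedMsa(
        ids=ids,
        rows=rows,
        reference_id=msa.reference_id,
        original_rows=original_rows,
        kept_columns=kept_columns,
        col_to_refpos=col_to_refpos,
        refpos_to_col=refpos_to_col,
    )


def identity(seq_a: str, seq_b: str) -> float:
    """Fraction of matching residues over columns where both are residues."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    both = (a != GAP_CODE) & (b != GAP_CODE)
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float((a[both] == b[both]).sum() / n)


def cluster_weights(tmsa: TrimmedMsa, threshold: float = 0.62) -> SequenceWeights:
    """Single-linkage identity clustering; weight = 1 / cluster size.

    Two sequences join the same cluster if connected through pairs with
    identity >= ``threshold``.
    """
    n = tmsa.n_sequences
    if n == 0:
        raise DegenerateInputError("no sequences to weight")
    enc = tmsa.encoded()
    residue = enc != GAP_CODE

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # vectorized pairwise identity, row i against all j > i
    for i in range(n - 1):
        both = residue[i] & residue[i + 1 :]
        matches = ((enc[i] == enc[i + 1 :]) & both).sum(axis=1)
        counts = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(counts > 0, matches / np.maximum(counts, 1), 0.0)
        for off in np.nonzero(ident >= threshold)[0]:
            union(i, i + 1 + int(off))

    roots = np.array([find(i) for i in range(n)])
    _, cluster_ids, sizes = np.unique(roots, return_inverse=True, return_counts=True)
    weights = 1.0 / sizes[cluster_ids]
    return SequenceWeights(
        ids=list(tmsa.ids),
        weights=weights.astype(float),
        threshold=threshold,
        cluster_ids=cluster_ids,
    )


def write_column_map_tsv(tmsa: TrimmedMsa, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tref_position\n")
        for c in range(tmsa.n_columns):
            fh.write(f"{c}\t{tmsa.col_to_refpos[c]}\n")


def write_weights_tsv(weights: SequenceWeights, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tweight\tcluster\n")
        for sid, w, c in zip(weights.ids, weights.weights, weights.cluster_ids):
            fh.write(f"{sid}\t{w:.10g}\t{int(c)}\n")
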