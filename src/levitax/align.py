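"""Pairwise protein alignment and pairwise amino-acid identity (PAAI).

PAAI is the demarcation statistic of the whole framework: percentage of
identical residues between two globally aligned proteins, with the denominator
restricted to columns between the first and last residue–residue pair
(terminal gap overhangs excluded, so incomplete contig ends are not
penalized).

Alignments are Needleman–Wunsch (global) or Smith–Waterman (local, score only)
with affine gaps over BLOSUM62 by default; a gap of length k costs
gap_open + k·gap_extend.  Ties are broken deterministically: residue pair over
gap-in-a over gap-in-b.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels
from .seq_io import ProteinRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@lru_cache(maxsize=8)
def substitution_matrix(name: str = DEFAULT_MATRIX) -> np.ndarray:
    """A 21×21 substitution matrix over ALPHABET (X included)."""
    try:
        m = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {name!r}") from exc
    out = np.zeros((21, 21))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a][b]
    return out


def encode(seq: str) -> np.ndarray:
    return np.array([_INDEX[c] for c in seq], dtype=np.int64)


def _encoded(p: ProteinRecord) -> np.ndarray:
    """Integer encoding, cached on the record (records are immutable in use)."""
    enc = getattr(p, "_enc", None)
    if enc is None or len(enc) != len(p.sequence):
        enc = encode(p.sequence)
        p._enc = enc
    return enc


@dataclass
class Alignment:
    """A global alignment of two proteins (gap character '-')."""

    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Needleman–Wunsch global alignment with affine gaps."""
    sub = substitution_matrix(matrix)
    score, ops = _kernels.nw_affine(
        _encoded(a), _encoded(b), sub, gap_open, gap_extend
    )
    rows_a, rows_b = [], []
    ia = ib = 0
    for op in ops:
        if op == 0:
            rows_a.append(a.sequence[ia])
            rows_b.append(b.sequence[ib])
            ia += 1
            ib += 1
        elif op == 1:  # gap in a
            rows_a.append("-")
            rows_b.append(b.sequence[ib])
            ib += 1
        else:  # gap in b
            rows_a.append(a.sequence[ia])
            rows_b.append("-")
            ia += 1
    return Alignment(a.id, b.id, "".join(rows_a), "".join(rows_b), float(score))


def _identity_from_ops(a_seq: str, b_seq: str, ops: np.ndarray) -> float:
    """Identity % over columns between the first and last residue pair."""
    diag = np.flatnonzero(ops == 0)
    if len(diag) == 0:
        return 0.0
    first, last = diag[0], diag[-1]
    span = ops[first : last + 1]
    ia = int(np.sum(ops[:first] == 2))  # a residues consumed in the overhang
    ib = int(np.sum(ops[:first] == 1))
    ident = 0
    for op in span:
        if op == 0:
            if a_seq[ia] == b_seq[ib]:
                ident += 1
            ia += 1
            ib += 1
        elif op == 1:
            ib += 1
        else:
            ia += 1
    return 100.0 * ident / len(span)


def paai(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Pairwise amino-acid identity in percent, in [0, 100]."""
    if a.sequence == b.sequence:
        return 100.0
    sub = substitution_matrix(matrix)
    _, ops = _kernels.nw_affine(
        _encoded(a), _encoded(b), sub, gap_open, gap_extend
    )
    return _identity_from_ops(a.sequence, b.sequence, ops)


def local_score_bits(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Smith–Waterman local alignment score in bits.

    BLOSUM62 scores are in half-bit units, so the raw optimum is halved.
    """
    sub = substitution_matrix(matrix)
    raw = _kernels.sw_score(
        _encoded(a), _encoded(b), sub, gap_open, gap_extend
    )
    return float(raw) / 2.0
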