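"""Reciprocal-best-hit homology between two protein sets.

One-to-one homology between a de-novo protein set and a reference set is
established conservatively: a pair is emitted only when each sequence is the
other's unique best hit by Smith-Waterman local alignment score and the
score clears a floor. Ties are excluded rather than broken arbitrarily,
since isoforms or closely related genes can share a single best hit.

The aligner is Bio.Align.PairwiseAligner in local mode with a named
substitution matrix (default BLOSUM62) and affine gaps: a gap of length k
scores -(gap_open + (k-1) * gap_extend). The acceptance floor is a raw
score, not an E-value: Karlin-Altschul statistics are deliberately out of
scope at desk-scale database sizes, so results are not BLAST-equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ConfigurationError, InputError
from .records import ProteinRecord

__all__ = ["AlignmentParams", "RbhPair", "local_align", "reciprocal_best_hits"]


@dataclass(frozen=True)
class AlignmentParams:
    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_score: int = 50

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ConfigurationError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ConfigurationError(
                "gap_extend must not exceed gap_open"
            )
        try:
            _load_matrix(self.substitution_matrix)
        except Exception as exc:
            raise ConfigurationError(
                f"unknown substitution matrix "
                f"{self.substitution_matrix!r}: {exc}"
            ) from exc


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aln = PairwiseAligner(mode="local")
    aln.substitution_matrix = _load_matrix(name)
    aln.open_gap_score = -float(gap_open)
    aln.extend_gap_score = -float(gap_extend)
    return aln


def _check_alphabet(seq: str, alphabet: str, label: str) -> None:
    if not seq:
        raise InputError(f"{label}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise InputError(
                f"{label}: residue {ch!r} at position {pos} is not in the "
                f"substitution matrix alphabet"
            )


def local_align(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> int:
    """Optimal Smith-Waterman local alignment score (non-negative)."""
    if params is None:
        params = AlignmentParams()
    matrix = _load_matrix(params.substitution_matrix)
    alphabet = str(matrix.alphabet)
    _check_alphabet(seq_a, alphabet, "seq_a")
    _check_alphabet(seq_b, alphabet, "seq_b")
    aln = _aligner(
        params.substitution_matrix, params.gap_open, params.gap_extend
    )
    # the empty alignment (score 0) is always admissible in local alignment
    return max(0, int(aln.score(seq_a, seq_b)))


class RbhPair(NamedTuple):
    id_a: str
    id_b: str
    score: int


class _BestHit(NamedTuple):
    index: int
    score: int
    tied: bool


def _best(scores: list[int]) -> _BestHit:
    top = max(scores)
    hits = [i for i, s in enumerate(scores) if s == top]
    return _BestHit(hits[0], top, len(hits) > 1)


def reciprocal_best_hits(
    set_a: list[ProteinRecord],
    set_b: list[ProteinRecord],
    params: AlignmentParams | None = None,
) -> list[RbhPair]:
    """Conservative one-to-one homology by reciprocal best hit.

    For every a in ``set_a`` the best hit in ``set_b`` is found by local
    alignment score, and vice versa; a pair is emitted iff both best hits are
    unique (no ties), reciprocal, and score at least ``params.min_score``.
    The output is symmetric in the two sets and maps each id at most once.
    """
    if params is None:
        params = AlignmentParams()
    if not set_a or not set_b:
        raise InputError("both protein sets must be non-empty")
    score = [
        [local_align(a.sequence, b.sequence, params) for b in set_b]
        for a in set_a
    ]
    best_in_b = [_best(row) for row in score]
    best_in_a = [
        _best([score[i][j] for i in range(len(set_a))])
        for j in range(len(set_b))
    ]
    pairs = []
    for i, hit in enumerate(best_in_b):
        if hit.tied or hit.score < params.min_score:
            continue
        j = hit.index
        back = best_in_a[j]
        if back.tied or back.index != i:
            continue
        pairs.append(RbhPair(set_a[i].id, set_b[j].id, hit.score))
    return pairs
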