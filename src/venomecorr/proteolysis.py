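"""Search-space construction and in-silico proteolysis.

Six-frame translation of assembled transcripts builds the protein search
space; enzymatic digestion enumerates candidate peptides with missed
cleavages; observed peptides are matched back to proteins by exact substring
containment.

Cleavage specificities follow the residue sets used for the searches:
trypsin after R and K, chymotrypsin after F, L, W and Y, Glu-C after D and E.
No "not before proline" exception is applied by default (it can be switched
on), and Glu-C can be restricted to E-only for the acidic-buffer dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple

from .errors import ConfigurationError, InputError
from .records import PeptideObservation, ProteinRecord

__all__ = [
    "CLEAVAGE_RESIDUES",
    "DigestionParams",
    "DigestPeptide",
    "six_frame_translate",
    "reverse_complement",
    "split_orfs",
    "digest",
    "match_peptides",
    "build_six_frame_database",
]

#: residues immediately N-terminal to each enzyme's cleavage sites
CLEAVAGE_RESIDUES: dict[str, str] = {
    "trypsin": "RK",
    "chymotrypsin": "FLWY",
    "glu-c": "DE",
    "glu-c-e-only": "E",
}

_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NT_OK = frozenset("ACGTN")


def _check_nt(sequence: str) -> None:
    for pos, ch in enumerate(sequence):
        if ch not in _NT_OK:
            raise InputError(
                f"invalid nucleotide {ch!r} at position {pos} "
                "(alphabet is A/C/G/T/N, uppercase)"
            )


def reverse_complement(sequence: str) -> str:
    _check_nt(sequence)
    return sequence.translate(_COMPLEMENT)[::-1]


def _translate_frame(sequence: str, offset: int) -> str:
    # trailing partial codon dropped; any codon not in the standard table
    # (i.e. containing N) yields X
    end = offset + 3 * ((len(sequence) - offset) // 3)
    return "".join(
        _CODONS.get(sequence[i : i + 3], "X") for i in range(offset, end, 3)
    )


def six_frame_translate(nt_sequence: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Returns a dict keyed by frame {+1, +2, +3, -1, -2, -3}; reverse frames
    translate the reverse complement. Stop codons appear as ``*``; codons
    containing N translate to ``X``.
    """
    _check_nt(nt_sequence)
    if len(nt_sequence) < 3:
        raise InputError(
            f"sequence too short to translate ({len(nt_sequence)} nt < 3)"
        )
    rc = nt_sequence.translate(_COMPLEMENT)[::-1]
    return {
        1: _translate_frame(nt_sequence, 0),
        2: _translate_frame(nt_sequence, 1),
        3: _translate_frame(nt_sequence, 2),
        -1: _translate_frame(rc, 0),
        -2: _translate_frame(rc, 1),
        -3: _translate_frame(rc, 2),
    }


def split_orfs(translated: str, min_length: int = 1) -> list[str]:
    """Maximal stop-free segments of a translated frame, in order."""
    if min_length < 1:
        raise ConfigurationError(
            f"min_length must be >= 1, got {min_length}"
        )
    return [seg for seg in translated.split("*") if len(seg) >= min_length]


def build_six_frame_database(
    transcripts: list, min_orf_length: int = 30
) -> list[ProteinRecord]:
    """Six-frame protein search space from transcript records.

    Every stop-free segment of at least ``min_orf_length`` residues in any
    of the six frames becomes a candidate protein, tagged with its source
    transcript and frame. Ids are ``<transcript>|f<frame>|<index>``.
    """
    db: list[ProteinRecord] = []
    for tx in transcripts:
        frames = six_frame_translate(tx.sequence)
        for frame in (1, 2, 3, -1, -2, -3):
            for i, orf in enumerate(split_orfs(frames[frame], min_orf_length)):
                db.append(
                    ProteinRecord(
                        id=f"{tx.id}|f{frame:+d}|{i}",
                        sequence=orf,
                        source_transcript=tx.id,
                        frame=frame,
                    )
                )
    return db


@dataclass(frozen=True)
class DigestionParams:
    """Parameters for one enzymatic (or no-enzyme) digestion.

    ``enzyme="none"`` models the undigested venom sample used to recover
    naturally occurring peptides: the intact sequence is the only candidate
    and the missed-cleavage limit is ignored.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    exclude_proline: bool = False

    def __post_init__(self) -> None:
        if self.enzyme != "none" and self.enzyme not in CLEAVAGE_RESIDUES:
            raise ConfigurationError(
                f"unknown enzyme {self.enzyme!r}; known: "
                f"{sorted(CLEAVAGE_RESIDUES)} or 'none'"
            )
        if self.max_missed_cleavages < 0:
            raise ConfigurationError(
                "max_missed_cleavages must be non-negative"
            )
        if self.min_peptide_length < 1:
            raise ConfigurationError("min_peptide_length must be positive")
        if self.max_peptide_length < self.min_peptide_length:
            raise ConfigurationError(
                "max_peptide_length must be >= min_peptide_length"
            )


class DigestPeptide(NamedTuple):
    sequence: str
    missed_cleavages: int
    start: int


def cleavage_sites(sequence: str, params: DigestionParams) -> list[int]:
    """Internal cut positions (index of the residue after each cut)."""
    residues = CLEAVAGE_RESIDUES[params.enzyme]
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in residues:
            if params.exclude_proline and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def digest(sequence: str, params: DigestionParams) -> list[DigestPeptide]:
    """Enumerate enzymatic peptides with up to the allowed missed cleavages.

    Peptides are contiguous runs of fully-cleaved fragments spanning at most
    ``max_missed_cleavages`` internal cut sites, filtered to the configured
    length window; order is by start position then missed-cleavage count.
    """
    if not sequence:
        raise InputError("cannot digest an empty sequence")
    if "*" in sequence:
        raise InputError(
            f"sequence contains a stop character at position "
            f"{sequence.index('*')}; digest stop-free segments"
        )
    lo, hi = params.min_peptide_length, params.max_peptide_length
    if params.enzyme == "none":
        if lo <= len(sequence) <= hi:
            return [DigestPeptide(sequence, 0, 0)]
        return []
    bounds = [0] + cleavage_sites(sequence, params) + [len(sequence)]
    out: list[DigestPeptide] = []
    n_frag = len(bounds) - 1
    for j in range(n_frag):
        for k in range(params.max_missed_cleavages + 1):
            if j + k + 1 > n_frag:
                break
            start, end = bounds[j], bounds[j + k + 1]
            if end - start > hi:
                break  # extending only lengthens the peptide
            if end - start >= lo:
                out.append(DigestPeptide(sequence[start:end], k, start))
    return out


def _canon(seq: str, il_equivalent: bool) -> str:
    return seq.replace("I", "L") if il_equivalent else seq


_INDEX_K = 4  # seed k-mer length for substring matching


def match_peptides(
    observations: list[PeptideObservation],
    proteins: list[ProteinRecord],
    il_equivalent: bool = False,
) -> list[PeptideObservation]:
    """Fill each observation's match set by exact substring containment.

    A peptide matches every protein whose full sequence contains it (with I
    and L conflated when ``il_equivalent``). Matching is seeded with a k-mer
    index over the protein sequences and verified by direct comparison, so
    results are identical to a full substring scan. Observations matching no
    protein are returned with an empty match set (``unmatched`` flag).
    """
    index: dict[str, list[tuple[int, int]]] = {}
    seqs = [_canon(p.sequence, il_equivalent) for p in proteins]
    for pi, seq in enumerate(seqs):
        for i in range(len(seq) - _INDEX_K + 1):
            index.setdefault(seq[i : i + _INDEX_K], []).append((pi, i))
    out: list[PeptideObservation] = []
    cache: dict[str, frozenset[str]] = {}
    for obs in observations:
        pep = _canon(obs.peptide, il_equivalent)
        hit = cache.get(pep)
        if hit is None:
            ids: set[str] = set()
            if len(pep) >= _INDEX_K:
                for pi, i in index.get(pep[: _INDEX_K], ()):
                    if seqs[pi].startswith(pep, i):
                        ids.add(proteins[pi].id)
            else:  # peptides shorter than the seed: direct scan
                for pi, seq in enumerate(seqs):
                    if pep in seq:
                        ids.add(proteins[pi].id)
            hit = frozenset(ids)
            cache[pep] = hit
        out.append(obs.with_matches(hit))
    return out
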