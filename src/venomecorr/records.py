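"""Shared domain records.

These light dataclasses are the currency passed between pipeline stages:
transcripts with fragment counts and FPKM, proteins in the search space,
identified peptides with their protein match sets, and per-protein abundance
scores (fractionally attributed identification events per residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InputError

__all__ = [
    "TranscriptRecord",
    "ProteinRecord",
    "PeptideObservation",
    "AbundanceScore",
]


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with its nucleotide sequence and quantification.

    ``length_nt`` must equal ``len(sequence)`` whenever a sequence is carried;
    fragment counts and FPKM default to the unquantified state.
    """

    id: str
    sequence: str = ""
    length_nt: int = 0
    fragment_count: int = 0
    fpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.sequence and self.length_nt == 0:
            object.__setattr__(self, "length_nt", len(self.sequence))
        if self.sequence and self.length_nt != len(self.sequence):
            raise InputError(
                f"transcript {self.id!r}: length_nt={self.length_nt} does not "
                f"match sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein in the search space.

    ``effective_length`` is the mature length used for abundance scoring:
    the full sequence minus an annotated N-terminal signal peptide. Matching
    always runs against the full ``sequence``; only scoring uses the
    effective length.
    """

    id: str
    sequence: str
    source_transcript: str | None = None
    frame: int | None = None
    is_contaminant: bool = False
    signal_peptide_length: int = 0

    def __post_init__(self) -> None:
        if self.signal_peptide_length < 0:
            raise InputError(
                f"protein {self.id!r}: negative signal_peptide_length"
            )
        if self.effective_length <= 0:
            raise InputError(
                f"protein {self.id!r}: effective length "
                f"{self.effective_length} is not positive (sequence length "
                f"{len(self.sequence)}, signal peptide "
                f"{self.signal_peptide_length})"
            )
        if (self.frame is None) != (self.source_transcript is None):
            raise InputError(
                f"protein {self.id!r}: frame and source_transcript must be "
                "given together"
            )

    @property
    def effective_length(self) -> int:
        return len(self.sequence) - self.signal_peptide_length


@dataclass(frozen=True)
class PeptideObservation:
    """An identified peptide with its identification-event count.

    ``count`` sums identification events over runs; ``matches`` is the set of
    search-space protein ids containing the peptide as a substring, filled by
    :func:`venomecorr.proteolysis.match_peptides`.
    """

    peptide: str
    count: int
    enzyme: str = "none"
    sample: str = "S1"
    matches: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.peptide:
            raise InputError("empty peptide sequence in observation")
        if self.count <= 0:
            raise InputError(
                f"peptide {self.peptide!r}: count must be positive"
            )

    @property
    def multiplicity(self) -> int:
        return len(self.matches)

    @property
    def unmatched(self) -> bool:
        return not self.matches

    def with_matches(self, matches: frozenset[str]) -> "PeptideObservation":
        return replace(self, matches=frozenset(matches))


@dataclass(frozen=True)
class AbundanceScore:
    """Length-normalized protein abundance from fractional spectral counts.

    ``score = adjusted_count / effective_length`` -- identification events,
    shared events split equally over all matching proteins, per residue of
    mature protein. Deliberately NOT normalized by the experiment-wide total:
    peptides elute and are detected independently of one another, unlike
    sequencing reads competing for flow-cell positions.
    """

    protein_id: str
    adjusted_count: float
    effective_length: int
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if self.effective_length <= 0:
            raise InputError(
                f"protein {self.protein_id!r}: effective_length must be "
                "positive"
            )
        if self.adjusted_count < 0:
            raise InputError(
                f"protein {self.protein_id!r}: negative adjusted_count"
            )

    @property
    def score(self) -> float:
        return self.adjusted_count / self.effective_length
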