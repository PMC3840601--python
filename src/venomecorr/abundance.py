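"""Protein abundance from fractionally-attributed peptide counts.

The abundance score for a protein is the total number of peptide
identification events attributed to it, divided by its mature (effective)
length: identification events per residue. An event whose peptide matches
several proteins is split equally among them ("adjusted counts"), so the sum
of adjusted counts always equals the sum of raw counts. The score is NOT
normalized by the experiment-wide total number of events: with adequate
chromatographic separation peptides are detected independently of one
another, so a per-experiment total would only couple otherwise independent
measurements.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError
from .records import AbundanceScore, PeptideObservation, ProteinRecord

__all__ = ["adjusted_counts", "abundance_scores", "scores_to_frame"]


def adjusted_counts(
    observations: list[PeptideObservation],
    distinct_peptides: bool = False,
) -> dict[str, float]:
    """Fractionally attribute observation counts to proteins.

    Each observation contributes ``count / multiplicity`` to every protein in
    its match set. With ``distinct_peptides=True`` each observation counts as
    a single peptide species instead of its identification-event count.

    Raises
    ------
    InputError
        If any observation is unmatched (empty match set); unmatched peptides
        must be filtered out before scoring.
    """
    out: dict[str, float] = {}
    for obs in observations:
        if obs.multiplicity == 0:
            raise InputError(
                f"unmatched observation {obs.peptide!r} "
                "(empty match set); filter unmatched peptides before scoring"
            )
        value = 1.0 if distinct_peptides else float(obs.count)
        share = value / obs.multiplicity
        for pid in obs.matches:
            out[pid] = out.get(pid, 0.0) + share
    return out


def abundance_scores(
    adjusted: dict[str, float],
    proteins: list[ProteinRecord],
    use_effective_length: bool = True,
) -> list[AbundanceScore]:
    """Length-normalize adjusted counts into per-protein abundance scores.

    Every protein in ``proteins`` receives a score (0 when unobserved).
    ``use_effective_length=False`` divides by the full sequence length
    instead of the mature length.
    """
    known = {p.id for p in proteins}
    orphans = sorted(set(adjusted) - known)
    if orphans:
        raise InputError(
            f"adjusted counts for proteins with no record (no length): "
            f"{orphans[:5]}{'...' if len(orphans) > 5 else ''}"
        )
    scores = []
    for p in proteins:
        length = p.effective_length if use_effective_length else len(p.sequence)
        scores.append(
            AbundanceScore(
                protein_id=p.id,
                adjusted_count=adjusted.get(p.id, 0.0),
                effective_length=length,
                is_contaminant=p.is_contaminant,
            )
        )
    return scores


def scores_to_frame(scores: list[AbundanceScore]) -> pd.DataFrame:
    """Tabular view of scores (protein_id, adjusted_count, length, score)."""
    return pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in scores],
            "adjusted_count": [s.adjusted_count for s in scores],
            "effective_length": [s.effective_length for s in scores],
            "score": [s.score for s in scores],
            "is_contaminant": [s.is_contaminant for s in scores],
        }
    )
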