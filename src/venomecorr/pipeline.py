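"""End-to-end pipeline driver.

Composes the stages in study order: FPKM quantification -> low-abundance
retention filter -> six-frame search-space construction (transcripts +
contaminant panel) -> peptide matching -> fractional length-normalized
scoring -> bootstrap contaminant threshold -> transcript-protein
correlation, with an optional reciprocal-best-hit robustness comparison
against a reference protein set. Every output file carries a provenance
header (version, config hash, seed) and reruns with the same configuration
are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import abundance_scores, adjusted_counts, scores_to_frame
from .contaminants import BootstrapConfig, apply_threshold, bootstrap_threshold
from .correlation import correlate, pair_and_transform
from .errors import InputError
from .io import config_hash, header_lines, read_fasta, read_tsv_table, write_tsv_table
from .proteolysis import build_six_frame_database, match_peptides
from .quant import compute_fpkm, filter_low_abundance
from .rbh import AlignmentParams, reciprocal_best_hits
from .records import PeptideObservation, ProteinRecord, TranscriptRecord

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    transcript_fasta: str
    counts_tsv: str
    peptides_tsv: str
    contaminant_fasta: str
    output_dir: str
    reference_fasta: str | None = None
    fpkm_threshold: float = 1.0
    min_orf_length: int = 30
    il_equivalent: bool = False
    transform: str = "log10"
    confidence: float = 0.999
    n_boot: int = 10_000
    statistic: str = "mean"
    min_rbh_score: int = 50
    seed: int = 0

    def required_paths(self) -> list[str]:
        paths = [
            self.transcript_fasta,
            self.counts_tsv,
            self.peptides_tsv,
            self.contaminant_fasta,
        ]
        if self.reference_fasta:
            paths.append(self.reference_fasta)
        return paths


@dataclass
class PipelineResult:
    correlation: object
    threshold: float
    n_retained: int
    n_filtered: int
    outputs: dict[str, Path] = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    for p in config.required_paths():
        if not Path(p).exists():
            raise InputError(f"input file does not exist: {p}")
    transcripts = [
        TranscriptRecord(id=rid, sequence=seq)
        for rid, seq in read_fasta(config.transcript_fasta)
    ]
    counts = read_tsv_table(config.counts_tsv, ["transcript_id", "fragments"])
    peptides = read_tsv_table(
        config.peptides_tsv, ["peptide", "count", "enzyme", "sample"]
    )
    contaminants = [
        ProteinRecord(id=rid, sequence=seq, is_contaminant=True)
        for rid, seq in read_fasta(config.contaminant_fasta)
    ]
    return transcripts, counts, peptides, contaminants


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages and write every intermediate table plus a run log."""
    transcripts, counts, peptide_table, contaminants = _load_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the analysis parameters only; the output location is not part
    # of the analysis, so runs into different directories stay identical
    cfg_hash = config_hash(
        {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "output_dir"
        }
    )
    head = header_lines(__version__, cfg_hash, config.seed)
    log: list[str] = [*head]
    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        write_tsv_table(df, path, head)
        outputs[name] = path

    # --- transcript quantification -------------------------------------
    lengths = {t.id: t.length_nt for t in transcripts}
    counts_s = pd.Series(
        counts["fragments"].to_numpy(), index=counts["transcript_id"].astype(str)
    )
    fpkm = compute_fpkm(counts_s, lengths, "auto")
    retained_tx = filter_low_abundance(fpkm, config.fpkm_threshold)
    emit(
        "fpkm.tsv",
        pd.DataFrame(
            {
                "transcript_id": fpkm.index,
                "fpkm": fpkm.to_numpy(),
                "retained": [i in retained_tx for i in fpkm.index],
            }
        ),
    )
    log.append(
        f"fpkm: {len(fpkm)} transcripts in, {len(retained_tx)} retained at "
        f"FPKM >= {config.fpkm_threshold}"
    )

    # --- search space and matching --------------------------------------
    search_space = (
        build_six_frame_database(transcripts, config.min_orf_length)
        + contaminants
    )
    log.append(
        f"search space: {len(search_space)} entries "
        f"({len(contaminants)} contaminants)"
    )
    observations = [
        PeptideObservation(
            peptide=str(r.peptide),
            count=int(r.count),
            enzyme=str(r.enzyme),
            sample=str(r.sample),
        )
        for r in peptide_table.itertuples()
    ]
    matched = match_peptides(observations, search_space, config.il_equivalent)
    usable = [o for o in matched if not o.unmatched]
    log.append(
        f"match: {len(matched)} observations, {len(usable)} matched, "
        f"{len(matched) - len(usable)} unmatched (excluded)"
    )
    emit(
        "matched_peptides.tsv",
        pd.DataFrame(
            {
                "peptide": [o.peptide for o in usable],
                "count": [o.count for o in usable],
                "enzyme": [o.enzyme for o in usable],
                "sample": [o.sample for o in usable],
                "multiplicity": [o.multiplicity for o in usable],
                "matches": [";".join(sorted(o.matches)) for o in usable],
            }
        ),
    )

    # --- scoring ---------------------------------------------------------
    adjusted = adjusted_counts(usable)
    scores = abundance_scores(adjusted, search_space)
    emit("scores.tsv", scores_to_frame(scores))

    # --- contaminant threshold ------------------------------------------
    contaminant_scores = [s.score for s in scores if s.is_contaminant]
    boot_cfg = BootstrapConfig(
        confidence=config.confidence,
        n_boot=config.n_boot,
        statistic=config.statistic,
        seed=config.seed,
    )
    if len(contaminant_scores) >= 2:
        boot = bootstrap_threshold(contaminant_scores, boot_cfg)
        threshold = boot.threshold
        log.append(
            f"threshold: {threshold:.6g} (CI [{boot.ci_lower:.6g}, "
            f"{boot.ci_upper:.6g}] from {boot.n_contaminants} contaminants)"
        )
    else:
        threshold = 0.0
        log.append("threshold: 0 (fewer than 2 contaminant scores)")
    partition = apply_threshold(scores, threshold)
    emit("retained.tsv", scores_to_frame(partition.retained))
    emit("filtered.tsv", scores_to_frame(partition.filtered))
    emit("contaminant_scores.tsv", scores_to_frame(partition.contaminant))
    log.append(
        f"filter: {len(partition.retained)} retained, "
        f"{len(partition.filtered)} below threshold"
    )
    report = [
        *[f"# {h}" for h in head],
        f"threshold: {threshold!r}",
        f"confidence: {config.confidence}",
        f"n_boot: {config.n_boot}",
        f"statistic: {config.statistic}",
        f"n_contaminants: {len(contaminant_scores)}",
    ]
    (outdir / "threshold_report.txt").write_text("\n".join(report) + "\n")
    outputs["threshold_report.txt"] = outdir / "threshold_report.txt"

    # --- correlation ------------------------------------------------------
    pid_tx = {p.id: p.source_transcript for p in search_space}
    link = {s.protein_id: pid_tx[s.protein_id] for s in partition.retained}
    # one predicted protein per transcript: its best-scoring retained ORF
    best_by_tx: dict[str, object] = {}
    for s in partition.retained:
        tx = link.get(s.protein_id)
        if tx not in retained_tx or s.score <= 0:
            continue
        cur = best_by_tx.get(tx)
        if cur is None or s.score > cur.score:
            best_by_tx[tx] = s
    score_table = {s.protein_id: s.score for s in best_by_tx.values()}
    fpkm_map = {i: float(v) for i, v in fpkm.items()}
    pairs, pairing = pair_and_transform(
        fpkm_map,
        score_table,
        link,
        transform=config.transform,
        fpkm_threshold=config.fpkm_threshold,
    )
    result = correlate(pairs, config.transform)
    scatter_ids = sorted(score_table)
    emit(
        "scatter.tsv",
        pd.DataFrame(
            {
                "protein_id": scatter_ids,
                "transcript_id": [link[p] for p in scatter_ids],
                "fpkm": [fpkm_map[link[p]] for p in scatter_ids],
                "score": [score_table[p] for p in scatter_ids],
            }
        ),
    )
    log.append(
        f"correlate: r={result.r:.4f} p={result.p_value:.3g} "
        f"n={result.n_pairs} transform={result.transform} "
        f"(excluded: low_fpkm={pairing.excluded_low_fpkm} "
        f"zero_fpkm={pairing.excluded_zero_fpkm} "
        f"zero_score={pairing.excluded_zero_score})"
    )

    # --- optional RBH robustness check ------------------------------------
    if config.reference_fasta:
        reference = [
            ProteinRecord(id=rid, sequence=seq)
            for rid, seq in read_fasta(config.reference_fasta)
        ]
        retained_records = [
            p for p in search_space if p.id in score_table
        ]
        if retained_records:
            rbh_pairs = reciprocal_best_hits(
                retained_records,
                reference,
                AlignmentParams(min_score=config.min_rbh_score),
            )
            emit(
                "rbh_pairs.tsv",
                pd.DataFrame(
                    {
                        "id_a": [p.id_a for p in rbh_pairs],
                        "id_b": [p.id_b for p in rbh_pairs],
                        "score": [p.score for p in rbh_pairs],
                    }
                ),
            )
            log.append(f"rbh: {len(rbh_pairs)} reciprocal pairs")

    summary = [
        *[f"# {h}" for h in head],
        f"r: {result.r!r}",
        f"p_value: {result.p_value!r}",
        f"n_pairs: {result.n_pairs}",
        f"transform: {result.transform}",
        f"threshold: {threshold!r}",
        f"retained_transcripts: {len(retained_tx)}",
        f"retained_proteins: {len(partition.retained)}",
    ]
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    outputs["summary.txt"] = outdir / "summary.txt"
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    outputs["run.log"] = outdir / "run.log"

    return PipelineResult(
        correlation=result,
        threshold=threshold,
        n_retained=len(partition.retained),
        n_filtered=len(partition.filtered),
        outputs=outputs,
    )
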