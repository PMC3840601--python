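"""Synthetic venom-gland datasets with known ground truth.

The generator emulates the statistical structure of a venom-gland study:
transcript abundances spanning ~six orders of magnitude (log-uniform by
default), one secreted protein per transcript (random open reading frames),
a small panel of laboratory contaminant proteins sitting low in the
abundance distribution, multi-protease digestion (trypsin / chymotrypsin /
Glu-C plus an undigested sample for naturally occurring peptides), and an
LC/MS-like detection model in which a candidate peptide's expected
identification-event count grows with protein abundance and carries
multiplicative log-normal noise:

    E[count] = kappa * abundance**detection_exponent * exp(N(0, sigma))

with the realized count Poisson. Everything is reproducible from a single
seed; the three sampling operations consume independent sub-streams so each
is individually deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .proteolysis import CLEAVAGE_RESIDUES, DigestionParams, digest, six_frame_translate
from .records import PeptideObservation, ProteinRecord, TranscriptRecord

__all__ = [
    "GeneratorConfig",
    "VenomeTruth",
    "sample_venome",
    "simulate_fragment_counts",
    "simulate_peptide_observations",
    "write_venome",
]

_KNOWN_ENZYMES = tuple(CLEAVAGE_RESIDUES) + ("none",)

# sense codons of the standard code (no stops), fixed order for determinism
_SENSE_CODONS = tuple(
    c
    for c in (
        a + b + d
        for a in "TCAG"
        for b in "TCAG"
        for d in "TCAG"
    )
    if c not in ("TAA", "TAG", "TGA")
)

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic venome.

    Defaults emulate the study's structure: 300 transcripts log-uniform over
    six decades of relative abundance, a paired-end library of 10^6
    fragments, ten contaminants at the 5% abundance quantile, three
    proteases plus a no-enzyme sample, and two allowed missed cleavages.
    ``detection_rate`` (kappa) is the expected identification events per
    candidate peptide per unit relative abundance.
    """

    n_transcripts: int = 300
    abundance_log10_range: tuple[float, float] = (0.0, 6.0)
    length_range_nt: tuple[int, int] = (240, 1500)
    total_fragments: int = 1_000_000
    n_contaminants: int = 10
    contaminant_length_range: tuple[int, int] = (100, 600)
    contaminant_abundance_quantile: float = 0.05
    detection_rate: float = 1e5
    detection_exponent: float = 1.0
    detection_noise_sigma: float = 0.5
    enzymes: tuple[str, ...] = ("trypsin", "chymotrypsin", "glu-c", "none")
    max_missed_cleavages: int = 2
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    paralog_fraction: float = 0.0
    paralog_identity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise ConfigurationError("n_transcripts must be non-negative")
        lo, hi = self.abundance_log10_range
        if hi < lo:
            raise ConfigurationError(
                f"abundance_log10_range upper < lower: {self.abundance_log10_range}"
            )
        llo, lhi = self.length_range_nt
        if llo <= 0 or lhi < llo:
            raise ConfigurationError(
                f"length_range_nt must be positive and ordered: {self.length_range_nt}"
            )
        if llo % 3 or lhi % 3:
            raise ConfigurationError(
                f"length_range_nt bounds must be multiples of 3: {self.length_range_nt}"
            )
        if llo < 9:
            raise ConfigurationError(
                "length_range_nt lower bound must allow start + codon + stop (>= 9)"
            )
        if self.total_fragments <= 0:
            raise ConfigurationError("total_fragments must be positive")
        if self.n_contaminants < 0:
            raise ConfigurationError("n_contaminants must be non-negative")
        if not 0.0 < self.contaminant_abundance_quantile < 1.0:
            raise ConfigurationError(
                "contaminant_abundance_quantile must be in (0, 1)"
            )
        if self.detection_rate < 0:
            raise ConfigurationError("detection_rate must be non-negative")
        if self.detection_exponent < 0:
            raise ConfigurationError("detection_exponent must be non-negative")
        if self.detection_noise_sigma < 0:
            raise ConfigurationError(
                "detection_noise_sigma must be non-negative"
            )
        unknown = set(self.enzymes) - set(_KNOWN_ENZYMES)
        if unknown:
            raise ConfigurationError(
                f"unknown enzymes {sorted(unknown)}; known: {_KNOWN_ENZYMES}"
            )
        if self.max_missed_cleavages < 0:
            raise ConfigurationError("max_missed_cleavages must be non-negative")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ConfigurationError("paralog_fraction must be in [0, 1]")
        if not 0.0 <= self.paralog_identity <= 1.0:
            raise ConfigurationError("paralog_identity must be in [0, 1]")


@dataclass(frozen=True)
class VenomeTruth:
    """Ground truth for one synthetic venome.

    ``transcript_abundance`` holds true relative abundances summing to 1;
    ``protein_abundance`` assigns each protein its abundance (equal to its
    transcript's for biological proteins, the configured low quantile for
    contaminants).
    """

    transcripts: list[TranscriptRecord]
    proteins: list[ProteinRecord]
    transcript_abundance: dict[str, float]
    protein_abundance: dict[str, float]
    contaminant_ids: frozenset[str]
    config: GeneratorConfig = field(default_factory=GeneratorConfig)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Start codon, ``n_codons - 2`` random sense codons, one stop codon."""
    inner = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in inner) + stop


def _mutate_orf(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Point-substitute codons (sense-to-sense) at rate ``1 - identity``."""
    codons = [seq[i : i + 3] for i in range(3, len(seq) - 3, 3)]
    for k in range(len(codons)):
        if rng.random() > identity:
            codons[k] = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
    return seq[:3] + "".join(codons) + seq[-3:]


def sample_venome(config: GeneratorConfig) -> VenomeTruth:
    """Draw one synthetic venome: transcripts, proteins, contaminants.

    Relative transcript abundances are log-uniform over
    ``abundance_log10_range`` and normalized to sum to 1. Each transcript is
    a random open reading frame; its protein is the frame +1 translation
    (stop removed). A ``paralog_fraction`` of transcripts are mutated copies
    of earlier ones, inducing shared peptides downstream. Contaminants are
    random amino-acid sequences placed at the configured quantile of the
    biological abundance distribution.
    """
    rng = _rng(config, 1)
    n = config.n_transcripts
    transcripts: list[TranscriptRecord] = []
    proteins: list[ProteinRecord] = []
    tx_abund: dict[str, float] = {}
    pr_abund: dict[str, float] = {}

    lo, hi = config.abundance_log10_range
    raw = 10.0 ** rng.uniform(lo, hi, size=n)
    rel = raw / raw.sum() if n else raw

    llo, lhi = config.length_range_nt
    codon_counts = rng.integers(llo // 3, lhi // 3 + 1, size=n)
    sequences: list[str] = []
    for i in range(n):
        make_paralog = (
            i > 0 and config.paralog_fraction > 0
            and rng.random() < config.paralog_fraction
        )
        if make_paralog:
            template = sequences[rng.integers(0, i)]
            seq = _mutate_orf(rng, template, config.paralog_identity)
        else:
            seq = _random_orf(rng, int(codon_counts[i]))
        sequences.append(seq)

    for i, seq in enumerate(sequences):
        tid = f"TX{i:05d}"
        transcripts.append(TranscriptRecord(id=tid, sequence=seq))
        tx_abund[tid] = float(rel[i])
        protein = six_frame_translate(seq)[1].rstrip("*")
        pid = f"{tid}.p"
        proteins.append(
            ProteinRecord(
                id=pid, sequence=protein, source_transcript=tid, frame=1
            )
        )
        pr_abund[pid] = float(rel[i])

    contaminant_ids = []
    if config.n_contaminants:
        if n == 0:
            raise ConfigurationError(
                "n_contaminants > 0 requires n_transcripts > 0 (contaminant "
                "abundance is a quantile of the biological distribution)"
            )
        c_abund = float(
            np.quantile(rel, config.contaminant_abundance_quantile)
        )
        clo, chi = config.contaminant_length_range
        for j in range(config.n_contaminants):
            # contaminants are ordinary proteins (keratins, added proteases...):
            # draw them as ORF translations so their residue composition
            # matches the rest of the proteome, not a uniform alphabet
            length = int(rng.integers(clo, chi + 1))
            seq = six_frame_translate(_random_orf(rng, length + 2))[1].rstrip("*")
            cid = f"CONTAM{j:03d}"
            proteins.append(
                ProteinRecord(id=cid, sequence=seq, is_contaminant=True)
            )
            pr_abund[cid] = c_abund
            contaminant_ids.append(cid)

    return VenomeTruth(
        transcripts=transcripts,
        proteins=proteins,
        transcript_abundance=tx_abund,
        protein_abundance=pr_abund,
        contaminant_ids=frozenset(contaminant_ids),
        config=config,
    )


def simulate_fragment_counts(truth: VenomeTruth) -> pd.DataFrame:
    """Multinomial fragment counts per transcript.

    Category probabilities are proportional to true abundance times
    transcript length (longer transcripts shed more fragments); counts sum
    exactly to ``config.total_fragments``.
    """
    if not truth.transcripts:
        raise InputError("cannot simulate fragment counts without transcripts")
    rng = _rng(truth.config, 2)
    ids = [t.id for t in truth.transcripts]
    weights = np.array(
        [truth.transcript_abundance[t.id] * t.length_nt for t in truth.transcripts]
    )
    probs = weights / weights.sum()
    counts = rng.multinomial(truth.config.total_fragments, probs)
    return pd.DataFrame({"transcript_id": ids, "fragments": counts})


def simulate_peptide_observations(
    truth: VenomeTruth, digestion: DigestionParams | None = None
) -> list[PeptideObservation]:
    """LC/MS-like peptide identification events for every protein.

    Candidate peptides come from in-silico digestion of each protein with
    each configured enzyme (deduplicated per protein and enzyme); each
    candidate's expected count is
    ``kappa * abundance**exponent * exp(N(0, sigma))`` and the realized
    count is Poisson. Zero-count candidates are omitted; counts of the same
    (peptide, enzyme) arising from different proteins are summed, as they
    would be indistinguishable in a real experiment.
    """
    config = truth.config
    if digestion is not None:
        if digestion.enzyme not in config.enzymes:
            raise ConfigurationError(
                f"digestion enzyme {digestion.enzyme!r} is not in "
                f"config.enzymes {config.enzymes}"
            )
        enzymes: tuple[str, ...] = (digestion.enzyme,)
        base = digestion
    else:
        enzymes = config.enzymes
        base = DigestionParams(
            max_missed_cleavages=config.max_missed_cleavages,
            min_peptide_length=config.min_peptide_length,
            max_peptide_length=config.max_peptide_length,
        )
    rng = _rng(config, 3)
    kappa = config.detection_rate
    totals: dict[tuple[str, str], int] = {}
    for protein in truth.proteins:
        abundance = truth.protein_abundance[protein.id]
        rate = kappa * abundance**config.detection_exponent
        for enzyme in enzymes:
            params = replace(base, enzyme=enzyme)
            candidates = list(
                dict.fromkeys(p.sequence for p in digest(protein.sequence, params))
            )
            if not candidates:
                continue
            noise = (
                np.exp(rng.normal(0.0, config.detection_noise_sigma, len(candidates)))
                if config.detection_noise_sigma > 0
                else np.ones(len(candidates))
            )
            counts = rng.poisson(rate * noise)
            for pep, c in zip(candidates, counts):
                if c > 0:
                    key = (pep, enzyme)
                    totals[key] = totals.get(key, 0) + int(c)
    return [
        PeptideObservation(peptide=pep, count=c, enzyme=enz, sample="S1")
        for (pep, enz), c in sorted(totals.items())
    ]


def write_venome(truth: VenomeTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the generated dataset as the downstream file contract.

    Produces transcripts.fasta, proteins.fasta, contaminants.fasta,
    fragments.tsv, peptides.tsv and truth.tsv in ``outdir`` and returns the
    paths. Peptide observations are simulated with the config's detection
    model; fragment counts with its multinomial model.
    """
    from .io import write_fasta, write_tsv_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "proteins": outdir / "proteins.fasta",
        "contaminants": outdir / "contaminants.fasta",
        "fragments": outdir / "fragments.tsv",
        "peptides": outdir / "peptides.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(
        [(t.id, t.sequence) for t in truth.transcripts], paths["transcripts"]
    )
    write_fasta(
        [(p.id, p.sequence) for p in truth.proteins if not p.is_contaminant],
        paths["proteins"],
    )
    write_fasta(
        [(p.id, p.sequence) for p in truth.proteins if p.is_contaminant],
        paths["contaminants"],
    )
    write_tsv_table(simulate_fragment_counts(truth), paths["fragments"])
    obs = simulate_peptide_observations(truth)
    write_tsv_table(
        pd.DataFrame(
            {
                "peptide": [o.peptide for o in obs],
                "count": [o.count for o in obs],
                "enzyme": [o.enzyme for o in obs],
                "sample": [o.sample for o in obs],
            }
        ),
        paths["peptides"],
    )
    write_tsv_table(
        pd.DataFrame(
            {
                "id": list(truth.protein_abundance),
                "true_abundance": list(truth.protein_abundance.values()),
                "is_contaminant": [
                    pid in truth.contaminant_ids
                    for pid in truth.protein_abundance
                ],
            }
        ),
        paths["truth"],
    )
    return paths
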