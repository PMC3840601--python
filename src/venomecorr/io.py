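"""File formats: FASTA for sequences, commented TSV for tables.

All tables are tab-separated with a header row; lines starting with ``#``
are comments and every file written by the pipeline begins with a comment
header recording the package version, a hash of the configuration, and the
seed, so runs are auditable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv_table",
    "write_tsv_table",
    "config_hash",
    "header_lines",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (id, sequence) pairs.

    The id is the header token up to the first whitespace; wrapping is
    irrelevant. Duplicate ids and non-FASTA leading content are errors.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: expected FASTA header line "
                    f"starting with '>', got {line.strip()[:30]!r}"
                )
            break
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    seen: set[str] = set()
    dups = []
    for rid, _ in records:
        if rid in seen:
            dups.append(rid)
        seen.add(rid)
    if dups:
        raise ParseError(f"{path}: duplicate ids: {sorted(set(dups))}")
    return records


def write_fasta(
    records: list[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    seqs = [
        SeqRecord(Seq(seq), id=str(rid), description="")
        for rid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_tsv_table(
    path: str | Path, required_columns: list[str] | None = None
) -> pd.DataFrame:
    """Read a commented TSV table, checking the schema if given."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ParseError(
                f"{path}: missing required columns {missing}; "
                f"found {list(df.columns)}"
            )
    return df


def write_tsv_table(
    df: pd.DataFrame, path: str | Path, header: list[str] | None = None
) -> None:
    """Write a TSV table, optionally preceded by '#'-prefixed header lines."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def config_hash(config_mapping: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canonical = json.dumps(config_mapping, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def header_lines(version: str, cfg_hash: str, seed: int) -> list[str]:
    """Standard provenance header for every pipeline output file."""
    return [f"venomecorr {version}", f"config {cfg_hash}", f"seed {seed}"]
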