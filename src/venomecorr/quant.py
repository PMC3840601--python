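"""Transcript quantification: FPKM and the low-abundance retention filter.

FPKM (fragments per kilobase of transcript per million fragments sequenced)
is computed from fragment counts and full transcript lengths::

    fpkm_i = count_i * 1e9 / (length_nt_i * library_size)

No effective-length correction is applied: the input table is assumed to be
fragment-level (paired-end units) already, and the full transcript length is
the normalizer. Transcripts with FPKM below a threshold (default 1.0) are
removed; a value exactly equal to the threshold is retained.
"""

from __future__ import annotations

from collections.abc import Mapping

import pandas as pd

from .errors import ConfigurationError, InputError, UndefinedValueError

__all__ = ["compute_fpkm", "filter_low_abundance", "fpkm_percent"]


def _as_series(table, value_name: str) -> pd.Series:
    """Coerce a mapping / Series / two-column DataFrame to a float Series."""
    if isinstance(table, pd.DataFrame):
        if table.shape[1] != 2:
            raise InputError(
                f"{value_name} table must have exactly two columns "
                f"(id, {value_name}); got {list(table.columns)}"
            )
        s = pd.Series(
            table.iloc[:, 1].to_numpy(), index=table.iloc[:, 0].astype(str)
        )
    elif isinstance(table, pd.Series):
        s = table.copy()
        s.index = s.index.astype(str)
    elif isinstance(table, Mapping):
        s = pd.Series({str(k): v for k, v in table.items()})
    else:
        raise InputError(f"unsupported {value_name} table type {type(table)}")
    dup = s.index[s.index.duplicated()].unique().tolist()
    if dup:
        raise InputError(f"duplicate ids in {value_name} table: {dup}")
    return s.astype(float)


def compute_fpkm(counts, lengths, library_size: int | str = "auto") -> pd.Series:
    """Compute FPKM for every transcript in ``counts``.

    Parameters
    ----------
    counts
        Fragment counts per transcript id (mapping, Series, or two-column
        DataFrame).
    lengths
        Transcript lengths in nucleotides, keyed by id. Every id in ``counts``
        must be present.
    library_size
        Total mapped fragments; ``"auto"`` uses the sum of ``counts``.

    Returns
    -------
    pandas.Series
        FPKM indexed by transcript id, in the order of ``counts``.
    """
    c = _as_series(counts, "fragment_count")
    ln = _as_series(lengths, "length_nt")
    if (c < 0).any():
        bad = c.index[c < 0].tolist()
        raise InputError(f"negative fragment counts for ids: {bad}")
    if (ln <= 0).any():
        bad = ln.index[ln <= 0].tolist()
        raise InputError(f"non-positive lengths for ids: {bad}")
    missing = c.index.difference(ln.index).tolist()
    if missing:
        raise InputError(f"ids with counts but no length: {missing}")
    if library_size == "auto":
        library_size = int(c.sum())
    if not isinstance(library_size, (int,)) or isinstance(library_size, bool):
        raise InputError(f"library_size must be an integer or 'auto'")
    if library_size <= 0:
        raise InputError(f"library_size must be positive, got {library_size}")
    fpkm = c * 1e9 / (ln.reindex(c.index) * library_size)
    fpkm.name = "fpkm"
    return fpkm


def filter_low_abundance(fpkm, threshold: float = 1.0) -> set[str]:
    """Ids retained by the low-abundance filter (FPKM >= threshold).

    Transcripts with FPKM strictly less than ``threshold`` are removed,
    so a transcript sitting exactly on the threshold survives.
    """
    if threshold < 0:
        raise ConfigurationError(
            f"threshold must be non-negative, got {threshold}"
        )
    s = _as_series(fpkm, "fpkm")
    if (s < 0).any():
        raise InputError("negative FPKM values in table")
    return set(s.index[s >= threshold])


def fpkm_percent(fpkm, id_subset) -> float:
    """Percentage of total FPKM carried by ``id_subset``.

    Used for percent-of-transcriptome summaries (e.g. the share of a toxin
    class). Returns 0.0 for an empty subset.
    """
    s = _as_series(fpkm, "fpkm")
    subset = {str(i) for i in id_subset}
    unknown = subset - set(s.index)
    if unknown:
        raise InputError(f"subset ids not in FPKM table: {sorted(unknown)}")
    total = float(s.sum())
    if total == 0.0:
        raise UndefinedValueError(
            "total FPKM is zero; percentage undefined"
        )
    if not subset:
        return 0.0
    return 100.0 * float(s.loc[sorted(subset)].sum()) / total
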