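"""Contaminant-derived abundance threshold.

Laboratory contaminants (cRAP-style entries such as human keratins) enter
samples during preparation and should be present at much lower levels than
genuine venom proteins. Their abundance scores therefore define a noise
floor: we bootstrap a 99.9% confidence interval around the contaminant
scores and filter every protein scoring below its upper bound.

Percentiles use the inverse empirical CDF (numpy's "higher"/"lower"
methods), so on small discrete resample spaces the bootstrap agrees exactly
with exhaustive enumeration of all n^n resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError, InputError
from .records import AbundanceScore

__all__ = [
    "BootstrapConfig",
    "ThresholdResult",
    "ThresholdPartition",
    "bootstrap_threshold",
    "apply_threshold",
]

_STATISTICS = {"mean": np.mean, "median": np.median}


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings for the contaminant threshold.

    ``interval="ci"`` (default) is the percentile bootstrap CI of the chosen
    statistic of the contaminant scores. ``interval="tolerance"`` instead
    bootstraps the upper tail of the score distribution itself (per-resample
    empirical quantile at ``confidence``, averaged over resamples) -- the
    alternative reading of an "interval around the abundance scores".
    """

    confidence: float = 0.999
    n_boot: int = 10_000
    statistic: str = "mean"
    interval: str = "ci"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ConfigurationError(
                f"confidence must be in (0, 1), got {self.confidence}"
            )
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if self.statistic not in _STATISTICS:
            raise ConfigurationError(
                f"statistic must be one of {sorted(_STATISTICS)}, "
                f"got {self.statistic!r}"
            )
        if self.interval not in ("ci", "tolerance"):
            raise ConfigurationError(
                f"interval must be 'ci' or 'tolerance', got {self.interval!r}"
            )


class ThresholdResult(NamedTuple):
    threshold: float
    ci_lower: float
    ci_upper: float
    n_contaminants: int
    config: BootstrapConfig


def bootstrap_threshold(
    contaminant_scores, config: BootstrapConfig | None = None
) -> ThresholdResult:
    """Bootstrap the confidence interval of the contaminant abundance scores.

    Draws ``n_boot`` resamples (with replacement, same size), computes the
    statistic of each, and takes the percentile interval at
    ``(1-confidence)/2`` and ``1-(1-confidence)/2``; the threshold is the
    upper bound. With a single score the interval degenerates to that value
    (a warning is emitted). Fully reproducible from ``config.seed``.
    """
    if config is None:
        config = BootstrapConfig()
    scores = np.asarray(list(contaminant_scores), dtype=float)
    if scores.size == 0:
        raise InputError("empty contaminant score list")
    if not np.all(np.isfinite(scores)):
        raise InputError("non-finite contaminant scores")
    if np.any(scores < 0):
        raise InputError("negative contaminant scores")
    if scores.size == 1:
        warnings.warn(
            "only one contaminant score; confidence interval degenerates "
            "to that value",
            stacklevel=2,
        )
        v = float(scores[0])
        return ThresholdResult(v, v, v, 1, config)
    rng = np.random.default_rng(config.seed)
    n = scores.size
    idx = rng.integers(0, n, size=(config.n_boot, n))
    resamples = scores[idx]
    alpha = 1.0 - config.confidence
    if config.interval == "ci":
        stats = _STATISTICS[config.statistic](resamples, axis=1)
        lower = float(np.quantile(stats, alpha / 2.0, method="lower"))
        upper = float(np.quantile(stats, 1.0 - alpha / 2.0, method="higher"))
    else:  # tolerance: bootstrap the upper tail of the score distribution
        per_resample = np.quantile(
            resamples, config.confidence, axis=1, method="higher"
        )
        upper = float(np.mean(per_resample))
        lower = float(
            np.mean(np.quantile(resamples, alpha, axis=1, method="lower"))
        )
    return ThresholdResult(upper, lower, upper, n, config)


class ThresholdPartition(NamedTuple):
    retained: list[AbundanceScore]
    filtered: list[AbundanceScore]
    contaminant: list[AbundanceScore]


def apply_threshold(
    scores: list[AbundanceScore],
    threshold: float,
    contaminant_ids: frozenset[str] | set[str] = frozenset(),
) -> ThresholdPartition:
    """Partition scored proteins at the contaminant-derived threshold.

    Biological proteins with ``score >= threshold`` are retained; those below
    are filtered. Proteins flagged contaminant (by id set or by their record
    flag) are reported separately and never enter the retained set.
    """
    if not np.isfinite(threshold) or threshold < 0:
        raise InputError(
            f"threshold must be finite and non-negative, got {threshold}"
        )
    retained, filtered, contam = [], [], []
    for s in scores:
        if s.is_contaminant or s.protein_id in contaminant_ids:
            contam.append(s)
        elif s.score >= threshold:
            retained.append(s)
        else:
            filtered.append(s)
    return ThresholdPartition(retained, filtered, contam)
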