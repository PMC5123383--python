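"""Median-of-ratios library-size normalization.

Samples sequenced at different depths need rescaling before their counts
can be compared.  The scaling factor of a sample is the median, over genes,
of the ratio between the sample's count and the gene's geometric mean count
across all samples (the estimator introduced by DESeq); genes with a zero
count in any sample are excluded from the reference geometric mean.  Fuzzy
counts are normalised by dividing the four trapezoid parameters by the
sample's factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fuzzy_counts import TrapezoidalCount

__all__ = ["SizeFactorSet", "NormalizationError", "size_factors", "normalize_trapezoid"]


class NormalizationError(ValueError):
    """No usable genes for the size-factor computation."""


@dataclass(frozen=True)
class SizeFactorSet:
    """Per-sample scaling factors (all positive).

    ``source`` records which punctual counts fed the computation
    ("centroid" or "unique").
    """

    factors: pd.Series
    source: str = "centroid"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise NormalizationError(f"size factors must be positive: {dict(self.factors)}")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])

    def items(self):
        return self.factors.items()


def size_factors(counts: pd.DataFrame, source: str = "centroid") -> SizeFactorSet:
    """Median-of-ratios size factors from a gene x sample count matrix.

    Only genes with a positive count in every sample contribute: their log
    counts are centred by the per-gene mean log count (the log geometric
    mean) and the factor of a sample is ``exp`` of the median of the centred
    values.  The median of an even number of genes is the arithmetic mean of
    the two middle values.
    """
    counts = counts.astype(float)
    if counts.empty or counts.shape[1] == 0:
        raise NormalizationError("empty count matrix")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has a positive count in every sample; consider centroid "
            "counts or a total-count fallback"
        )
    logc = np.log(counts[positive])
    log_geomean = logc.mean(axis=1)
    log_ratios = logc.sub(log_geomean, axis=0)
    factors = np.exp(log_ratios.median(axis=0))
    factors.name = "size_factor"
    return SizeFactorSet(factors, source)


def normalize_trapezoid(t: TrapezoidalCount, factor: float) -> TrapezoidalCount:
    """Divide the four trapezoid parameters by a positive scaling factor."""
    if not (np.isfinite(factor) and factor > 0):
        raise NormalizationError(f"scaling factor must be positive, got {factor!r}")
    return t.scaled(factor)
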