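"""Between-sample normalization of spectral counts (N-SC style).

Each sample column is rescaled so that its total equals a common target —
the mean (default) or median of the input column totals — which removes
per-sample loading/depth differences while preserving within-sample
proportions.  Normalizing an already-normalized matrix is a no-op up to
floating point (idempotence).
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .matrix import SpectralCountMatrix


def normalize_counts(
    matrix: SpectralCountMatrix,
    target: Literal["mean", "median"] = "mean",
) -> SpectralCountMatrix:
    """Scale every sample column to the common target total.

    Raises ``ValueError`` if any column total is zero (an empty sample cannot
    be rescaled).
    """
    totals = matrix.counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample columns cannot be normalized: {empty}")
    target_total = float(totals.mean() if target == "mean" else totals.median())
    factors = target_total / totals
    normalized = matrix.counts * factors
    return matrix.with_counts(normalized, normalized=True)
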