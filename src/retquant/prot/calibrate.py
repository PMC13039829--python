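"""Empirical calibration of the fold-change significance threshold.

Technical/control replicate groups (e.g. a split of wild-type samples)
define the null spread of abundance ratios.  Restricting to the
inner-quartile abundance range (where spectral counting is most stable),
the threshold is the 99th percentile of |ln ratio| on a natural-log scale,
clamped to the declared [1.5, 2.0] window; the ln-ln Pearson correlation R
between the two control splits and the achieved coverage are reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import SpectralCountMatrix


@dataclass
class FcCalibration:
    threshold: float
    r_lnln: float
    fraction_within: float
    clamp_window: tuple[float, float]
    n_proteins: int
    raw_threshold: float

    def __post_init__(self) -> None:
        lo, hi = self.clamp_window
        if not lo <= self.threshold <= hi:
            raise ValueError("threshold outside the clamp window")


def calibrate_fc_threshold(
    matrix: SpectralCountMatrix,
    control_split: tuple[Sequence[str], Sequence[str]],
    *,
    clamp_window: tuple[float, float] = (1.5, 2.0),
    coverage: float = 0.99,
    min_proteins: int = 20,
) -> FcCalibration:
    """Derive the fold-change window from a user-declared control split.

    ``control_split`` names two disjoint sample subsets treated as technical
    replicates of the same condition.  Proteins with a nonpositive mean in
    either split are dropped, the abundance range is restricted to the inner
    quartiles, and the threshold is ``exp(q_coverage(|ln ratio|))`` clamped
    to ``clamp_window``.  Raises ``ValueError`` if fewer than ``min_proteins``
    remain (unstable calibration).
    """
    ids_a, ids_b = (list(s) for s in control_split)
    if len(ids_a) < 1 or len(ids_b) < 1 or set(ids_a) & set(ids_b):
        raise ValueError("control split must be two disjoint nonempty sample sets")
    mean_a = matrix.counts[ids_a].mean(axis=1).to_numpy()
    mean_b = matrix.counts[ids_b].mean(axis=1).to_numpy()

    ok = (mean_a > 0) & (mean_b > 0)
    mean_a, mean_b = mean_a[ok], mean_b[ok]
    abundance = (mean_a + mean_b) / 2.0
    q1, q3 = np.quantile(abundance, [0.25, 0.75])
    inner = (abundance >= q1) & (abundance <= q3)
    mean_a, mean_b = mean_a[inner], mean_b[inner]
    n = mean_a.size
    if n < min_proteins:
        raise ValueError(
            f"only {n} proteins in the inner-quartile range (< {min_proteins}): "
            "calibration would be unstable"
        )

    ln_a, ln_b = np.log(mean_a), np.log(mean_b)
    r = float(np.corrcoef(ln_a, ln_b)[0, 1])
    ln_ratio = ln_a - ln_b
    # "higher" interpolation guarantees the stated coverage on the data itself
    raw = float(np.exp(np.quantile(np.abs(ln_ratio), coverage, method="higher")))
    lo, hi = clamp_window
    threshold = float(np.clip(raw, lo, hi))
    ratios = np.exp(ln_ratio)
    fraction = float(np.mean((ratios >= 1.0 / threshold) & (ratios <= threshold)))
    return FcCalibration(
        threshold=threshold,
        r_lnln=r,
        fraction_within=fraction,
        clamp_window=clamp_window,
        n_proteins=n,
        raw_threshold=raw,
    )
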