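"""Per-protein statistics for spectral-count differential expression.

Three statistics are combined into the differential-expression call: a
signal-to-noise weight W built from group means and standard deviations, a
one-tail unequal-variance (Welch) t-test, and a group-mean fold change.  The
weight follows the microarray signal-to-noise form W = (mu1 - mu2) / d where
``d`` is either the sum of the group standard deviations (the classic
signal-to-noise denominator, the default here) or their difference (the form
sometimes printed, ill-defined when the spreads are equal and provided for
completeness behind ``denominator_mode="as_printed"``).
"""

from __future__ import annotations

import warnings
from typing import Literal, Sequence

import numpy as np
from scipy import special

DenominatorMode = Literal["sum", "as_printed"]


def _as_groups(x1: Sequence[float], x2: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a1, a2 = np.atleast_2d(np.asarray(x1, float)), np.atleast_2d(np.asarray(x2, float))
    if a1.shape[-1] < 2 or a2.shape[-1] < 2:
        raise ValueError("each group needs at least 2 replicates")
    return a1, a2


def sam_weight(
    x1: Sequence[float],
    x2: Sequence[float],
    denominator_mode: DenominatorMode = "sum",
) -> float | np.ndarray:
    """Signal-to-noise weight W between two replicate groups.

    ``x1``/``x2`` may be 1-D (one protein) or 2-D (proteins x replicates);
    the weight is computed row-wise.  A zero denominator yields signed
    infinity (with a warning), never NaN, so thresholding stays monotone.
    """
    a1, a2 = _as_groups(x1, x2)
    mu1, mu2 = a1.mean(axis=-1), a2.mean(axis=-1)
    d1, d2 = a1.std(axis=-1, ddof=1), a2.std(axis=-1, ddof=1)
    denom = d1 + d2 if denominator_mode == "sum" else d1 - d2
    num = mu1 - mu2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = num / denom
    zero_denom = denom == 0
    if np.any(zero_denom):
        warnings.warn("zero W denominator: reporting signed infinity", stacklevel=2)
        w = np.where(zero_denom & (num > 0), np.inf, w)
        w = np.where(zero_denom & (num < 0), -np.inf, w)
        w = np.where(zero_denom & (num == 0), 0.0, w)
    w = np.asarray(w)
    return float(w[0]) if w.size == 1 and np.asarray(x1).ndim == 1 else w


def welch_one_tail_p(x1: Sequence[float], x2: Sequence[float]) -> float | np.ndarray:
    """One-tail Welch t-test p-value, tail taken toward the observed difference.

    Uses the Welch-Satterthwaite degrees of freedom; identical groups give
    p = 0.5 (the symmetric null at zero).  Zero variance in both groups with
    equal means returns p = 1.0 by convention (flagged with a warning);
    zero variance with unequal means returns the smallest positive float.
    """
    a1, a2 = _as_groups(x1, x2)
    n1, n2 = a1.shape[-1], a2.shape[-1]
    m1, m2 = a1.mean(axis=-1), a2.mean(axis=-1)
    v1, v2 = a1.var(axis=-1, ddof=1), a2.var(axis=-1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = special.stdtr(df, -np.abs(t))
    degenerate = se2 == 0
    if np.any(degenerate):
        warnings.warn("zero variance in both groups", stacklevel=2)
        p = np.where(degenerate & (m1 == m2), 1.0, p)
        p = np.where(degenerate & (m1 != m2), np.finfo(float).tiny, p)
    p = np.asarray(p)
    return float(p[0]) if p.size == 1 and np.asarray(x1).ndim == 1 else p


def fold_change(
    x1: Sequence[float],
    x2: Sequence[float],
    pseudocount: float | Literal["auto"] = "auto",
) -> float | np.ndarray:
    """Group-mean abundance ratio mean(x1)/mean(x2).

    With ``pseudocount="auto"`` (default) 0.5 is added to both means only
    when either mean falls below 0.5, guaranteeing a finite ratio with
    minimal bias at realistic counts; a numeric pseudocount is always added.
    """
    a1 = np.atleast_2d(np.asarray(x1, float))
    a2 = np.atleast_2d(np.asarray(x2, float))
    if a1.shape[-1] < 1 or a2.shape[-1] < 1:
        raise ValueError("groups must be nonempty")
    m1, m2 = a1.mean(axis=-1), a2.mean(axis=-1)
    if pseudocount == "auto":
        c = np.where((m1 < 0.5) | (m2 < 0.5), 0.5, 0.0)
    else:
        c = float(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (m1 + c) / (m2 + c)
    fc = np.asarray(fc)
    return float(fc[0]) if fc.size == 1 and np.asarray(x1).ndim == 1 else fc


def hypergeom_enrichment_p(k: int, m: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(overlap >= k) for a set of size ``m``
    against ``n`` draws from a universe of ``N``."""
    if not (0 <= k <= min(m, n) and m <= N and n <= N):
        raise ValueError("inconsistent hypergeometric parameters")
    from scipy.stats import hypergeom

    return float(hypergeom.sf(k - 1, N, m, n))
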