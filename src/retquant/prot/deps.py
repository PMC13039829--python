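"""Triple-criterion differential-expression calls and set comparison.

A protein is called differentially expressed (DEP) only when all three
statistics pass jointly: |W| above the signal-to-noise cutoff, one-tail
Welch p below the level, and fold change outside the calibrated window
(>= cut or <= 1/cut).  No across-protein multiple-testing correction is
applied to the call itself — the conjunction is the filter — but a
Benjamini-Hochberg column is emitted for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import SpectralCountMatrix
from .stats import DenominatorMode, fold_change, sam_weight, welch_one_tail_p


@dataclass(frozen=True)
class DepThresholds:
    w_cut: float = 0.8       # on |W|
    p_cut: float = 0.05      # one-tail level
    fc_cut: float = 1.5      # calibrated window edge; pass if FC >= cut or <= 1/cut

    def __post_init__(self) -> None:
        if self.fc_cut < 1.0:
            raise ValueError("fc_cut must be >= 1")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def call_deps(
    matrix: SpectralCountMatrix,
    thresholds: DepThresholds | None = None,
    *,
    denominator_mode: DenominatorMode = "sum",
    allow_unnormalized: bool = False,
) -> pd.DataFrame:
    """Per-protein DEP table for a two-group normalized count matrix.

    Columns: group means and sample standard deviations, W, one-tail p,
    FC (group1/group2), direction, the three pass flags, ``is_dep`` (their
    conjunction) and a BH-adjusted p for reference.  Refuses unnormalized
    input unless ``allow_unnormalized=True``.
    """
    thr = thresholds or DepThresholds()
    if not matrix.normalized and not allow_unnormalized:
        raise ValueError(
            "matrix is not normalized; normalize_counts() first or pass "
            "allow_unnormalized=True"
        )
    labels = matrix.group_labels
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1, g2 = labels
    x1, x2 = matrix.group_values(g1), matrix.group_values(g2)
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = np.asarray(sam_weight(x1, x2, denominator_mode))
        p = np.asarray(welch_one_tail_p(x1, x2))
        fc = np.asarray(fold_change(x1, x2))

    pass_sam = np.abs(w) > thr.w_cut
    pass_t = p < thr.p_cut
    pass_fc = (fc >= thr.fc_cut) | (fc <= 1.0 / thr.fc_cut)
    table = pd.DataFrame(
        {
            "mean_g1": x1.mean(axis=1),
            "mean_g2": x2.mean(axis=1),
            "sd_g1": x1.std(axis=1, ddof=1),
            "sd_g2": x2.std(axis=1, ddof=1),
            "W": w,
            "p_one_tail": p,
            "p_bh": _bh_adjust(p),
            "fc": fc,
            "direction": np.where(fc >= 1.0, "up", "down"),
            "pass_sam": pass_sam,
            "pass_t": pass_t,
            "pass_fc": pass_fc,
            "is_dep": pass_sam & pass_t & pass_fc,
        },
        index=pd.Index(matrix.protein_ids, name="protein_id"),
    )
    table.attrs["groups"] = (g1, g2)
    table.attrs["thresholds"] = thr
    table.attrs["denominator_mode"] = denominator_mode
    return table


def rank_and_compare(
    dep_a: pd.DataFrame,
    dep_b: pd.DataFrame,
    top_n: int = 40,
) -> dict:
    """Rank each DEP table by p-value and compare the called sets.

    Returns the two ranked top-``top_n`` DEP frames plus Venn-style counts:
    ``overlap`` (|A ∩ B|), ``unique_a`` and ``unique_b``.
    """
    def top(table: pd.DataFrame) -> pd.DataFrame:
        # stable sort after an index sort: deterministic tie-break by id
        deps = table[table["is_dep"]].sort_index()
        return deps.sort_values("p_one_tail", kind="mergesort").head(top_n)

    set_a = set(dep_a.index[dep_a["is_dep"]])
    set_b = set(dep_b.index[dep_b["is_dep"]])
    return {
        "top_a": top(dep_a),
        "top_b": top(dep_b),
        "n_dep_a": len(set_a),
        "n_dep_b": len(set_b),
        "overlap": len(set_a & set_b),
        "unique_a": len(set_a - set_b),
        "unique_b": len(set_b - set_a),
    }
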