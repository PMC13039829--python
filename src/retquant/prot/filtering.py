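"""Peptide-evidence filtering to a high-confidence protein count matrix.

Mirrors a Scaffold-style filter chain on an exported peptide table: peptides
must be longer than 5 residues, must not be singly charged (MH+1), and need
a peptide probability above 80%; proteins must retain at least 2 surviving
peptides, carry a protein probability above 99%, and an identification FDR
below 1%.  Per-protein spectral counts are the per-sample sums of the
surviving peptide counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .matrix import SpectralCountMatrix

REQUIRED_COLUMNS = (
    "protein_id",
    "peptide_sequence",
    "length_aa",
    "charge_state",
    "peptide_probability_pct",
    "protein_probability_pct",
    "protein_fdr_pct",
)


@dataclass(frozen=True)
class PeptideFilterThresholds:
    """Cutoffs of the identification filter; strictness follows the stated
    rules (length strictly greater, probabilities strictly greater, FDR
    strictly smaller)."""

    min_length_exclusive: int = 5
    banned_charge_states: tuple[int, ...] = (1,)
    min_peptide_probability_pct: float = 80.0
    min_peptides_per_protein: int = 2
    min_protein_probability_pct: float = 99.0
    max_protein_fdr_pct: float = 1.0


def filter_peptides(
    table: pd.DataFrame,
    sample_columns: Sequence[str],
    groups: Mapping[str, str],
    thresholds: PeptideFilterThresholds | None = None,
) -> tuple[list[str], SpectralCountMatrix]:
    """Apply the peptide- and protein-level rules; return surviving proteins
    and their summed spectral-count matrix.

    Raises ``KeyError`` naming the first missing required column.
    """
    thr = thresholds or PeptideFilterThresholds()
    for col in REQUIRED_COLUMNS + tuple(sample_columns):
        if col not in table.columns:
            raise KeyError(f"missing column: {col!r}")

    pep_ok = (
        (table["length_aa"] > thr.min_length_exclusive)
        & ~table["charge_state"].isin(thr.banned_charge_states)
        & (table["peptide_probability_pct"] > thr.min_peptide_probability_pct)
    )
    surviving = table.loc[pep_ok]

    per_protein = surviving.groupby("protein_id")
    n_peptides = per_protein["peptide_sequence"].nunique()
    prot_prob = per_protein["protein_probability_pct"].first()
    prot_fdr = per_protein["protein_fdr_pct"].first()
    keep = (
        (n_peptides >= thr.min_peptides_per_protein)
        & (prot_prob > thr.min_protein_probability_pct)
        & (prot_fdr < thr.max_protein_fdr_pct)
    )
    proteins = sorted(keep.index[keep])

    counts = (
        surviving[surviving["protein_id"].isin(proteins)]
        .groupby("protein_id")[list(sample_columns)]
        .sum()
        .loc[proteins]
    )
    matrix = SpectralCountMatrix(counts=counts, groups=dict(groups), normalized=False)
    return proteins, matrix
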