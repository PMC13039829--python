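"""Spectral-count matrix container used across the proteomics stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class SpectralCountMatrix:
    """Proteins x samples spectral counts with sample group labels.

    ``counts`` is indexed by protein id with one column per sample;
    ``groups`` maps every sample id to its group label.  ``normalized``
    records whether column-total normalization has been applied (normalized
    counts are fractional).
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.counts.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == label]

    def group_values(self, label: str) -> np.ndarray:
        """(proteins, n_samples) array of counts for one group."""
        return self.counts[self.samples_in_group(label)].to_numpy()

    def with_counts(self, counts: pd.DataFrame, *, normalized: bool | None = None) -> "SpectralCountMatrix":
        return SpectralCountMatrix(
            counts=counts,
            groups=dict(self.groups),
            normalized=self.normalized if normalized is None else normalized,
        )
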