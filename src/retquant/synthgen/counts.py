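"""Synthetic two-group spectral-count matrices with planted fold changes.

Counts follow a negative-binomial model parameterized by mean ``m`` and
dispersion ``alpha`` (variance ``m + alpha * m**2``), the standard
overdispersed model for spectral counts; ``alpha = 0`` is the deterministic
limit (counts equal the rounded mean), used to pin down expectations in
tests.  Per-protein baseline abundances are log-normal around
``baseline_mean`` so the matrix spans a realistic dynamic range; planted
effects multiply the first group's mean by the stated fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..prot.matrix import SpectralCountMatrix

DEFAULT_GROUPS = ("KO", "WT")


@dataclass(frozen=True)
class CountTableSpec:
    n_proteins: int = 2000
    group_sizes: tuple[int, int] = (4, 4)
    group_labels: tuple[str, str] = DEFAULT_GROUPS
    baseline_mean: float = 50.0
    abundance_sigma_ln: float = 1.0
    dispersion: float = 0.05
    library_size_factors: tuple[float, ...] | None = None
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("group_sizes must each be >= 2")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(fc <= 0 for fc in self.planted_effects.values()):
            raise ValueError("planted fold changes must be positive")
        n_samples = sum(self.group_sizes)
        if self.library_size_factors is not None and len(self.library_size_factors) != n_samples:
            raise ValueError("library_size_factors length must equal total sample count")


def protein_id(i: int) -> str:
    return f"P{i + 1:05d}"


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return np.rint(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def make_count_table(spec: CountTableSpec) -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Generate counts plus a truth table of per-protein planted effects.

    Returns the matrix (raw integer counts, unnormalized) and a tidy truth
    frame with columns ``protein_id``, ``base_mean`` and ``true_fc`` (the
    planted ratio of group-1 over group-2 means; 1.0 where nothing was
    planted).  Pure function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    ids = [protein_id(i) for i in range(n)]

    if spec.abundance_sigma_ln > 0:
        base = spec.baseline_mean * rng.lognormal(
            -spec.abundance_sigma_ln**2 / 2.0, spec.abundance_sigma_ln, size=n
        )
    else:
        base = np.full(n, spec.baseline_mean)

    fc = np.ones(n)
    for pid, effect in spec.planted_effects.items():
        try:
            fc[ids.index(pid)] = effect
        except ValueError:
            raise KeyError(f"planted effect for unknown protein {pid!r}") from None

    n1, n2 = spec.group_sizes
    factors = (
        np.ones(n1 + n2)
        if spec.library_size_factors is None
        else np.asarray(spec.library_size_factors, float)
    )
    sample_ids = [f"{spec.group_labels[0]}_{i + 1}" for i in range(n1)] + [
        f"{spec.group_labels[1]}_{i + 1}" for i in range(n2)
    ]
    groups = {s: spec.group_labels[0] if i < n1 else spec.group_labels[1]
              for i, s in enumerate(sample_ids)}

    means = np.empty((n, n1 + n2))
    means[:, :n1] = (base * fc)[:, None]
    means[:, n1:] = base[:, None]
    means *= factors[None, :]
    counts = _nb_draw(rng, means, spec.dispersion)

    matrix = SpectralCountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=sample_ids),
        groups=groups,
        normalized=False,
    )
    truth = pd.DataFrame({"protein_id": ids, "base_mean": base, "true_fc": fc})
    return matrix, truth
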