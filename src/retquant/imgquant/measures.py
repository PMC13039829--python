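"""Compartmental intensities, TUNEL counts, projection and ONL thickness."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label

from .layers import LayerMasks

COMPARTMENTS = ("onl", "opl", "is")


def project_stack(zstack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection across the slice axis (axis 0)."""
    stack = np.asarray(zstack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("z-stack must be a nonempty (slices, rows, cols) array")
    return stack.max(axis=0)


@dataclass
class IntensityResult:
    mean_intensity: dict[str, float]
    area_um2: dict[str, float]


def mean_intensity(
    channel: np.ndarray,
    masks: LayerMasks,
    compartments: tuple[str, ...] = COMPARTMENTS,
) -> IntensityResult:
    """Arithmetic mean pixel value and area under each compartment mask."""
    img = np.asarray(channel, dtype=float)
    if img.shape != masks.shape:
        raise ValueError("channel and masks have different shapes")
    means: dict[str, float] = {}
    areas: dict[str, float] = {}
    for comp in compartments:
        mask = getattr(masks, f"{comp}_mask")
        if not mask.any():
            raise ValueError(f"empty mask for requested compartment {comp!r}")
        means[comp] = float(img[mask].mean())
        areas[comp] = float(mask.sum()) * masks.pixel_size_um**2
    return IntensityResult(mean_intensity=means, area_um2=areas)


def count_tunel(
    tunel_channel: np.ndarray,
    region_mask: np.ndarray,
    *,
    pixel_size_um: float,
    nucleus_diameter_um: float = 5.0,
    blur_sigma_px: float = 1.0,
    threshold: float | None = None,
    size_gate: tuple[float, float] = (0.25, 4.0),
) -> int:
    """Count TUNEL-positive nuclei inside a region.

    Detected objects are 8-connected components of the thresholded channel
    whose area falls within ``size_gate`` times the nominal nucleus area;
    overlapping nuclei merged into one component count once.
    """
    img = np.asarray(tunel_channel, dtype=float)
    region = np.asarray(region_mask, dtype=bool)
    if img.shape != region.shape:
        raise ValueError("channel and region mask have different shapes")
    if not region.any():
        raise ValueError("region mask is empty")
    blurred = gaussian_filter(img, blur_sigma_px) if blur_sigma_px > 0 else img
    if threshold is None:
        lo, hi = blurred.min(), blurred.max()
        threshold = threshold_otsu(blurred) if hi > lo else hi
    binary = blurred > threshold
    labels = label(binary & region, connectivity=2)
    nominal_px = np.pi * (nucleus_diameter_um / 2.0 / pixel_size_um) ** 2
    lo_px, hi_px = size_gate[0] * nominal_px, size_gate[1] * nominal_px
    sizes = np.bincount(labels.ravel())[1:]
    return int(((sizes >= lo_px) & (sizes <= hi_px)).sum())


@dataclass
class ThicknessResult:
    per_position_thickness_um: list[float]
    mean_um: float
    positions: list[int]

    def __post_init__(self) -> None:
        if len(self.per_position_thickness_um) != len(self.positions):
            raise ValueError("positions and thicknesses differ in length")


def measure_onl_thickness(
    masks: LayerMasks,
    seed: int,
    *,
    n_positions: int = 3,
    grid_columns: int = 12,
    max_retries: int = 20,
) -> ThicknessResult:
    """ONL thickness at randomized grid positions.

    A grid of evenly spaced columns emulates a randomization overlay; a
    seeded generator picks ``n_positions`` of them without replacement and
    the thickness at each is the vertical pixel extent of the ONL mask times
    the pixel size.  Columns where the ONL is absent are resampled with a
    warning; after ``max_retries`` failures an error is raised.
    """
    rng = np.random.default_rng(seed)
    onl = masks.onl_mask
    n_cols = onl.shape[1]
    grid = np.linspace(0, n_cols - 1, grid_columns + 2, dtype=int)[1:-1]
    candidates = list(rng.permutation(grid))
    chosen: list[int] = []
    thicknesses: list[float] = []
    retries = 0
    while len(chosen) < n_positions:
        if not candidates or retries > max_retries:
            raise ValueError("ONL absent at too many sampled grid columns")
        col = int(candidates.pop(0))
        extent = int(onl[:, col].sum())
        if extent == 0:
            warnings.warn(f"ONL absent at column {col}; resampling", stacklevel=2)
            retries += 1
            continue
        chosen.append(col)
        thicknesses.append(extent * masks.pixel_size_um)
    return ThicknessResult(
        per_position_thickness_um=thicknesses,
        mean_um=float(np.mean(thicknesses)),
        positions=chosen,
    )
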