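"""Dendritic-sprouting quantification in the outer nuclear layer.

Rod-bipolar dendrites normally stop at the OPL; in degenerating retina they
sprout past the OPL/ONL boundary.  The measurement mirrors a tracing macro:
Gaussian blur, threshold, binary mask, skeletonization, and branch tracing.
Candidate sprouts are connected components of the thresholded signal inside
the ONL that are rooted at the OPL/ONL boundary; a candidate counts as a
sprout only when it penetrates the ONL by at least one nucleus diameter.
Total length is the calibrated 8-connected skeleton path length of retained
sprouts; density is retained sprout area over ONL area, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize

from .layers import LayerMasks


@dataclass(frozen=True)
class SproutingParams:
    """Tunable knobs of the sprout-tracing pipeline.

    ``blur_sigma_px``: pre-threshold Gaussian blur.  ``threshold``: fixed
    intensity cutoff, or None for Otsu on the blurred channel.
    ``nucleus_diameter_um`` sets the minimum ONL penetration for a candidate
    to count as a sprout (the "beyond one nucleus" rule).
    ``boundary_margin_px`` rows nearest the OPL/ONL boundary are excluded
    when forming components so that boundary bleed of the OPL signal does
    not bridge sprouts together; retained skeleton lengths are corrected by
    this margin.  ``min_branch_px`` drops sub-resolution skeleton fragments.
    """

    blur_sigma_px: float = 1.0
    threshold: float | None = None
    nucleus_diameter_um: float = 5.0
    min_penetration_um: float | None = None
    boundary_margin_px: int = 3
    min_branch_px: int = 3
    min_component_px: int = 6


@dataclass
class SproutingResult:
    total_length_um: float
    per_sprout_length_um: list[float]
    sprouted_area_um2: float
    density_pct: float
    n_sprouts: int

    def __post_init__(self) -> None:
        if self.n_sprouts != len(self.per_sprout_length_um):
            raise ValueError("n_sprouts must match the per-sprout list")
        if not np.isclose(self.total_length_um, sum(self.per_sprout_length_um)):
            raise ValueError("total length must equal the sum of per-sprout lengths")


def skeleton_length_px(skeleton: np.ndarray) -> float:
    """Calibrated 8-connected path length of a thin skeleton, in pixels.

    Orthogonal steps count 1, diagonal steps sqrt(2); a diagonal adjacency
    that is short-circuited by an orthogonal neighbour (an L-corner) is not
    double counted.
    """
    s = np.asarray(skeleton, dtype=bool)
    orth = (s[1:, :] & s[:-1, :]).sum() + (s[:, 1:] & s[:, :-1]).sum()
    d_main = s[1:, 1:] & s[:-1, :-1] & ~(s[1:, :-1] | s[:-1, 1:])
    d_anti = s[1:, :-1] & s[:-1, 1:] & ~(s[1:, 1:] | s[:-1, :-1])
    return float(orth + np.sqrt(2.0) * (d_main.sum() + d_anti.sum()))


def quantify_sprouting(
    bipolar_channel: np.ndarray,
    masks: LayerMasks,
    params: SproutingParams | None = None,
) -> SproutingResult:
    """Measure sprout lengths and sprouting density inside the ONL.

    Raises on shape mismatch between channel and masks and on an empty ONL
    mask.  A blank channel yields an all-zero result.
    """
    p = params or SproutingParams()
    img = np.asarray(bipolar_channel, dtype=float)
    if img.shape != masks.shape:
        raise ValueError("channel and masks have different shapes")
    onl = masks.onl_mask
    onl_area_px = int(onl.sum())
    if onl_area_px == 0:
        raise ValueError("ONL mask is empty")
    px = masks.pixel_size_um
    min_pen_um = (
        p.min_penetration_um if p.min_penetration_um is not None else p.nucleus_diameter_um
    )

    blurred = gaussian_filter(img, p.blur_sigma_px) if p.blur_sigma_px > 0 else img
    if p.threshold is not None:
        thr = p.threshold
    else:
        lo, hi = blurred.min(), blurred.max()
        thr = threshold_otsu(blurred) if hi > lo else hi  # constant image: empty mask
    binary = blurred > thr

    # OPL/ONL boundary row (vitreal ONL edge) and the excluded bleed margin.
    onl_rows = np.nonzero(onl.any(axis=1))[0]
    boundary_row = onl_rows.max()
    keep_rows = np.zeros(img.shape[0], dtype=bool)
    keep_rows[: boundary_row - p.boundary_margin_px + 1] = True
    core = binary & onl & keep_rows[:, None]

    labels = label(core, connectivity=2)
    per_lengths: list[float] = []
    area_px = 0
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < p.min_component_px:
            continue
        rows = np.nonzero(comp.any(axis=1))[0]
        # rooted: reaches the first kept row adjacent to the excluded margin
        if rows.max() < boundary_row - p.boundary_margin_px - 1:
            continue
        penetration_um = (boundary_row - rows.min() + 1) * px
        if penetration_um < min_pen_um:
            continue
        skel = skeletonize(comp)
        length_px = skeleton_length_px(skel)
        if length_px < p.min_branch_px:
            continue
        per_lengths.append((length_px + p.boundary_margin_px) * px)
        area_px += size

    total = float(sum(per_lengths))
    return SproutingResult(
        total_length_um=total,
        per_sprout_length_um=per_lengths,
        sprouted_area_um2=area_px * px**2,
        density_pct=100.0 * area_px / onl_area_px,
        n_sprouts=len(per_lengths),
    )
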