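"""Synthetic retinal-section phantoms with exact ground truth.

The phantom emulates a vertical cryosection of mouse retina imaged by
confocal microscopy: an inner-segment (IS) band, a nuclei-packed outer
nuclear layer (ONL), and an outer plexiform layer (OPL), with rod-bipolar
dendritic sprouts rising from the OPL into the ONL.  Every generated stack
comes with the exact quantities a downstream measurement should recover:
per-sprout polyline lengths, the sprouted area fraction of the ONL, the
compartment masks, and the number of TUNEL-positive nuclei.

Row 0 is the scleral (IS) side; rows increase toward the OPL.  Sprout
polylines are given in micrometres as ``(row_um, col_um)`` vertices and must
start inside the OPL band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, line
from skimage.morphology import dilation, disk as disk_footprint

from ..imgquant.layers import LayerMasks

CHANNELS = ("nuclei", "bipolar", "opl_marker", "is_marker", "tunel")

_DEFAULT_LEVELS: dict[str, tuple[float, float]] = {
    name: (200.0, 20.0) for name in CHANNELS
}


@dataclass(frozen=True)
class RetinaPhantomSpec:
    """Parameters of a synthetic retinal section.

    ``layer_boundaries`` are four ordered row coordinates (pixels) delimiting
    the IS, ONL and OPL bands: IS = [b0, b1), ONL = [b1, b2), OPL = [b2, b3).
    ``nucleus_density`` is nuclei per 100 µm² of ONL.  ``sprouts`` is a tuple
    of polylines, each a tuple of ``(row_um, col_um)`` vertices starting
    inside the OPL.  ``channel_levels`` maps channel name to
    ``(foreground, background)`` intensity.
    """

    image_height_px: int = 360
    image_width_px: int = 480
    pixel_size_um: float = 0.5
    layer_boundaries: tuple[int, int, int, int] = (20, 80, 280, 340)
    nucleus_density: float = 2.0
    nucleus_diameter_um: float = 5.0
    sprouts: tuple[tuple[tuple[float, float], ...], ...] = ()
    sprout_width_um: float = 1.5
    channel_levels: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LEVELS)
    )
    psf_sigma_um: float = 0.2
    noise_sigma: float = 8.0
    tunel_positive_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        b = self.layer_boundaries
        if len(b) != 4 or not all(b[i] < b[i + 1] for i in range(3)):
            raise ValueError("layer_boundaries must be four increasing rows")
        if b[3] > self.image_height_px:
            raise ValueError("layer_boundaries exceed image height")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.tunel_positive_count < 0:
            raise ValueError("tunel_positive_count must be >= 0")
        for name, (fg, bg) in self.channel_levels.items():
            if fg < 0 or bg < 0:
                raise ValueError(f"negative intensity for channel {name!r}")
        opl_lo_um = b[2] * self.pixel_size_um
        opl_hi_um = b[3] * self.pixel_size_um
        h_um = self.image_height_px * self.pixel_size_um
        w_um = self.image_width_px * self.pixel_size_um
        for i, poly in enumerate(self.sprouts):
            if len(poly) < 2:
                raise ValueError(f"sprout {i}: polyline needs >= 2 vertices")
            for r_um, c_um in poly:
                if not (0 <= r_um < h_um and 0 <= c_um < w_um):
                    raise ValueError(f"sprout {i}: vertex outside image")
            r0 = poly[0][0]
            if not (opl_lo_um <= r0 < opl_hi_um):
                raise ValueError(f"sprout {i}: polyline must start inside the OPL band")


@dataclass
class PhantomTruth:
    """Exact ground truth emitted alongside a phantom stack."""

    total_sprout_length_um: float
    per_sprout_length_um: list[float]
    sprouted_area_fraction_pct: float
    layer_masks: LayerMasks
    tunel_count: int
    nucleus_centers_px: np.ndarray | None = None
    tunel_centers_px: np.ndarray | None = None


def polyline_length_um(poly: Sequence[tuple[float, float]]) -> float:
    """Euclidean length of a polyline given in micrometre coordinates."""
    pts = np.asarray(poly, dtype=float)
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


def _raster_polyline(
    poly: Sequence[tuple[float, float]], shape: tuple[int, int],
    pixel_size_um: float, width_px: int,
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(poly, dtype=float) / pixel_size_um
    pts = np.clip(np.rint(pts).astype(int), 0, np.array(shape) - 1)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(r0, c0, r1, c1)
        mask[rr, cc] = True
    if width_px > 1:
        mask = dilation(mask, disk_footprint((width_px - 1) // 2))
    return mask


def _place_disks(
    rng: np.random.Generator, n: int, row_range: tuple[int, int],
    n_cols: int, radius_px: float, shape: tuple[int, int],
    min_separation_px: float = 0.0, max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly place ``n`` disk centres; optional minimum separation."""
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        r = rng.uniform(row_range[0] + radius_px, row_range[1] - radius_px)
        c = rng.uniform(radius_px, n_cols - radius_px)
        if min_separation_px > 0 and any(
            (r - r2) ** 2 + (c - c2) ** 2 < min_separation_px**2 for r2, c2 in centers
        ):
            continue
        centers.append((r, c))
    if len(centers) < n:
        raise RuntimeError("could not place the requested number of separated objects")
    mask = np.zeros(shape, dtype=bool)
    for r, c in centers:
        rr, cc = disk((r, c), radius_px, shape=shape)
        mask[rr, cc] = True
    return mask, np.asarray(centers)


def make_retina_phantom(spec: RetinaPhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Rasterize a retinal-section phantom.

    Returns a ``(5, H, W)`` float32 stack with channels ordered as
    ``CHANNELS`` (nuclei / bipolar marker / OPL synaptic marker / IS marker /
    TUNEL) and the exact :class:`PhantomTruth`.  The output is a pure
    function of the spec, including its seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    px = spec.pixel_size_um
    b0, b1, b2, b3 = spec.layer_boundaries

    def band(lo: int, hi: int) -> np.ndarray:
        m = np.zeros((h, w), dtype=bool)
        m[lo:hi, :] = True
        return m

    is_band, onl_band, opl_band = band(b0, b1), band(b1, b2), band(b2, b3)

    nuc_radius_px = spec.nucleus_diameter_um / 2.0 / px
    onl_area_um2 = onl_band.sum() * px**2
    n_nuclei = int(round(spec.nucleus_density * onl_area_um2 / 100.0))
    nuclei_mask, nuc_centers = _place_disks(
        rng, n_nuclei, (b1, b2), w, nuc_radius_px, (h, w)
    )

    width_px = max(1, round(spec.sprout_width_um / px))
    sprout_mask = np.zeros((h, w), dtype=bool)
    per_len = []
    for poly in spec.sprouts:
        sprout_mask |= _raster_polyline(poly, (h, w), px, width_px)
        per_len.append(polyline_length_um(poly))

    tunel_mask = np.zeros((h, w), dtype=bool)
    tunel_centers = np.empty((0, 2))
    if spec.tunel_positive_count > 0:
        tunel_mask, tunel_centers = _place_disks(
            rng, spec.tunel_positive_count, (b1, b2), w, nuc_radius_px,
            (h, w), min_separation_px=6 * nuc_radius_px,
        )

    fg_masks = {
        "nuclei": nuclei_mask,
        "bipolar": opl_band | sprout_mask,
        "opl_marker": opl_band,
        "is_marker": is_band,
        "tunel": tunel_mask,
    }
    psf_px = spec.psf_sigma_um / px
    stack = np.empty((len(CHANNELS), h, w), dtype=np.float32)
    for i, name in enumerate(CHANNELS):
        fg, bg = spec.channel_levels.get(name, _DEFAULT_LEVELS[name])
        img = np.where(fg_masks[name], fg, bg).astype(float)
        if psf_px > 0:
            img = gaussian_filter(img, psf_px)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        stack[i] = np.clip(img, 0.0, None)

    sprout_in_onl = sprout_mask & onl_band
    truth = PhantomTruth(
        total_sprout_length_um=float(sum(per_len)),
        per_sprout_length_um=per_len,
        sprouted_area_fraction_pct=100.0 * sprout_in_onl.sum() / onl_band.sum(),
        layer_masks=LayerMasks(
            onl_mask=onl_band, opl_mask=opl_band, is_mask=is_band,
            pixel_size_um=px, channels_used=CHANNELS,
        ),
        tunel_count=spec.tunel_positive_count,
        nucleus_centers_px=nuc_centers,
        tunel_centers_px=tunel_centers,
    )
    return stack, truth


def random_sprouts(
    n: int,
    spec_like: RetinaPhantomSpec,
    rng: np.random.Generator,
    *,
    length_um_range: tuple[float, float] = (20.0, 60.0),
    wobble_um: float = 3.0,
    n_segments: int = 4,
) -> tuple[tuple[tuple[float, float], ...], ...]:
    """Draw ``n`` mostly-vertical sprout polylines rising from the OPL.

    Each sprout starts just inside the OPL at a random column and climbs into
    the ONL with small lateral wobble, so its Euclidean length is close to
    (and its ONL penetration slightly less than) the drawn target length.
    """
    px = spec_like.pixel_size_um
    b2 = spec_like.layer_boundaries[2]
    start_row_um = b2 * px  # first OPL row
    w_um = spec_like.image_width_px * px
    margin = wobble_um + 2 * px
    sprouts = []
    for _ in range(n):
        target = rng.uniform(*length_um_range)
        col = rng.uniform(margin + length_um_range[1] * 0.3, w_um - margin - length_um_range[1] * 0.3)
        seg = target / n_segments
        pts = [(start_row_um, col)]
        for _ in range(n_segments):
            dx = rng.uniform(-wobble_um, wobble_um)
            dy = np.sqrt(max(seg**2 - dx**2, (0.5 * seg) ** 2))
            r, c = pts[-1]
            pts.append((r - dy, c + dx))
        sprouts.append(tuple(pts))
    return tuple(sprouts)
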