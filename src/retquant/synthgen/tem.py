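"""Synthetic electron-micrograph phantoms of photoreceptor terminals.

Rod spherules and cone pedicles are drawn as polygons containing elliptical
mitochondria; by default a rod terminal carries exactly one large
mitochondrion while cone terminals carry several smaller ones, matching the
wild-type ultrastructure of the mouse OPL.  The truth table records the
analytic polygon areas (shoelace) and mitochondrial areas (pi*a*b) so that
pixel-count morphometry can be validated against closed-form values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon as ShapelyPolygon, Point
from skimage.draw import ellipse, polygon as draw_polygon


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in micrometre coordinates: centre, semi-axes, rotation."""

    center_um: tuple[float, float]  # (row, col)
    a_um: float
    b_um: float
    rotation_rad: float = 0.0

    @property
    def area_um2(self) -> float:
        return float(np.pi * self.a_um * self.b_um)


@dataclass(frozen=True)
class Terminal:
    polygon_um: tuple[tuple[float, float], ...]  # (row, col) vertices
    terminal_type: str  # "rod" | "cone"
    mitochondria: tuple[Ellipse, ...] = ()


def shoelace_area_um2(vertices: Sequence[tuple[float, float]]) -> float:
    pts = np.asarray(vertices, dtype=float)
    r, c = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))) / 2.0)


@dataclass(frozen=True)
class TemPhantomSpec:
    """Terminals with their mitochondria, plus rasterization parameters."""

    terminals: tuple[Terminal, ...]
    image_height_px: int = 1200
    image_width_px: int = 1200
    pixel_size_um: float = 0.01
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for i, term in enumerate(self.terminals):
            if term.terminal_type not in ("rod", "cone"):
                raise ValueError(f"terminal {i}: type must be 'rod' or 'cone'")
            poly = ShapelyPolygon(term.polygon_um)
            for j, m in enumerate(term.mitochondria):
                if not poly.contains(_ellipse_boundary(m)):
                    raise ValueError(
                        f"terminal {i}: mitochondrion {j} escapes its terminal polygon"
                    )


def _ellipse_boundary(e: Ellipse, n: int = 64) -> ShapelyPolygon:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    cr, cc = e.center_um
    rot = e.rotation_rad
    rows = cr + e.a_um * np.cos(t) * np.cos(rot) - e.b_um * np.sin(t) * np.sin(rot)
    cols = cc + e.a_um * np.cos(t) * np.sin(rot) + e.b_um * np.sin(t) * np.cos(rot)
    return ShapelyPolygon(np.column_stack([rows, cols]))


def make_tem_phantom(
    spec: TemPhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Rasterize terminals and mitochondria.

    Returns ``(image, terminal_labels, mito_mask, truth)`` where ``image`` is
    a float32 grayscale micrograph-like rendering, ``terminal_labels`` an
    int32 label image (background 0, terminal i+1), ``mito_mask`` a boolean
    mask of all mitochondria, and ``truth`` a tidy table with one row per
    terminal carrying analytic areas and the per-terminal occupancy.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, px = spec.image_height_px, spec.image_width_px, spec.pixel_size_um

    labels = np.zeros((h, w), dtype=np.int32)
    mito_mask = np.zeros((h, w), dtype=bool)
    rows = []
    for i, term in enumerate(spec.terminals):
        pts = np.asarray(term.polygon_um, dtype=float) / px
        rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=(h, w))
        labels[rr, cc] = i + 1
        mito_areas = []
        for m in term.mitochondria:
            er, ec = np.asarray(m.center_um) / px
            rr, cc = ellipse(
                er, ec, m.a_um / px, m.b_um / px, shape=(h, w),
                rotation=m.rotation_rad,
            )
            mito_mask[rr, cc] = True
            mito_areas.append(m.area_um2)
        term_area = shoelace_area_um2(term.polygon_um)
        rows.append(
            {
                "terminal_id": i + 1,
                "terminal_type": term.terminal_type,
                "terminal_area_um2": term_area,
                "mito_count": len(mito_areas),
                "mito_areas_um2": mito_areas,
                "occupancy": sum(mito_areas) / term_area if term_area else np.nan,
            }
        )
    truth = pd.DataFrame(rows)

    # Micrograph-like rendering: bright embedding background, grey cytoplasm,
    # dark osmiophilic mitochondria.
    image = np.full((h, w), 200.0)
    image[labels > 0] = 130.0
    image[mito_mask] = 60.0
    image = gaussian_filter(image, 2.0)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return image.astype(np.float32), labels, mito_mask, truth


def random_tem_spec(
    rng: np.random.Generator,
    *,
    n_rod: int = 4,
    n_cone: int = 2,
    field_um: float = 12.0,
    pixel_size_um: float = 0.01,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> TemPhantomSpec:
    """Lay out non-overlapping terminals on a grid with jitter.

    Rod spherules get exactly one large mitochondrion; cone pedicles get 3-5
    smaller ones.
    """
    n = n_rod + n_cone
    side = int(np.ceil(np.sqrt(n)))
    cell = field_um / side
    order = rng.permutation(n)
    terminals = []
    for k in range(n):
        gi, gj = divmod(int(order[k]), side)
        cr = (gi + 0.5) * cell + rng.uniform(-0.05, 0.05) * cell
        cc = (gj + 0.5) * cell + rng.uniform(-0.05, 0.05) * cell
        is_rod = k < n_rod
        radius = cell * rng.uniform(0.30, 0.42) if not is_rod else cell * rng.uniform(0.22, 0.32)
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        radii = radius * (1 + rng.uniform(-0.12, 0.12, size=t.size))
        poly = tuple(
            (cr + r_ * np.sin(a), cc + r_ * np.cos(a)) for r_, a in zip(radii, t)
        )
        inner = radii.min() * 0.92
        if is_rod:
            a = inner * rng.uniform(0.55, 0.7)
            b = a * rng.uniform(0.6, 0.85)
            mitos = (Ellipse((cr, cc), a, b, rng.uniform(0, np.pi)),)
        else:
            n_mito = int(rng.integers(3, 6))
            mitos = []
            ang0 = rng.uniform(0, 2 * np.pi)
            for j in range(n_mito):
                ang = ang0 + 2 * np.pi * j / n_mito
                d = inner * 0.55
                a = inner * rng.uniform(0.16, 0.24)
                b = a * rng.uniform(0.6, 0.9)
                mitos.append(
                    Ellipse((cr + d * np.sin(ang), cc + d * np.cos(ang)), a, b,
                            rng.uniform(0, np.pi))
                )
            mitos = tuple(mitos)
        terminals.append(
            Terminal(polygon_um=poly, terminal_type="rod" if is_rod else "cone",
                     mitochondria=mitos)
        )
    hpx = int(np.ceil(field_um / pixel_size_um))
    return TemPhantomSpec(
        terminals=tuple(terminals), image_height_px=hpx, image_width_px=hpx,
        pixel_size_um=pixel_size_um, noise_sigma=noise_sigma, seed=seed,
    )
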