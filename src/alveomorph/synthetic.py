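"""Synthetic ground-truth images.

Two families:

*Wallpapers* — 2040x2040 binary images tiled with repetitions of a fixed
combination of geometric figures (white, playing the airspace role)
randomly arranged on a black background (the "septal" phase). Because the
figures' total area A and perimeter P are known exactly, the image has
exact theoretical read-outs

    VVsep_theory = (W^2 - A) / W^2
    Lm_theory    = 4 (1 - VVsep) W^2 / P  =  4 A / P   (pixels)

against which the counting pipeline is validated. For axis-aligned
squares and rectangles, intercept counting with axis-aligned test lines
estimates 4A/P without systematic error; for circles the counting
expectation is the mean chord pi*A/P, a factor pi/4 below the 4A/P
formula — supported, but flagged as a known discrepancy.

*Histology phantoms* — 680x680 grayscale fields that mimic lung
parenchyma: a septal wall network around polygonal airspaces, large
vessel-like regions, and small exudate-like particles, each with an exact
truth mask. They exercise the segmentation steps (thresholding, exudate
filtering, cleaning) with known answers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.morphology import disk as disk_footprint

from .errors import GenerationError, SamplingError
from .ingest import DEFAULT_SCALE_UM_PER_PX, FIELD_SIZE, FieldImage

WALLPAPER_WIDTH = 2040


@dataclass(frozen=True)
class FigureSpec:
    """One geometric figure: 'square' (side=width), 'rectangle'
    (width x height) or 'circle' (radius=width)."""

    kind: str
    width: int
    height: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("square", "rectangle", "circle"):
            raise GenerationError(f"unknown figure kind {self.kind!r}")
        if self.width < 1 or (self.height is not None and self.height < 1):
            raise GenerationError("figure dimensions must be >= 1 px")

    @property
    def bbox(self) -> tuple[int, int]:
        """(width, height) of the bounding box in pixels."""
        if self.kind == "square":
            return self.width, self.width
        if self.kind == "rectangle":
            return self.width, self.height or self.width
        return 2 * self.width + 1, 2 * self.width + 1  # circle, radius=width

    @property
    def area(self) -> float:
        """Analytic area (exact pixel count for squares/rectangles)."""
        if self.kind == "square":
            return float(self.width**2)
        if self.kind == "rectangle":
            return float(self.width * (self.height or self.width))
        return math.pi * self.width**2

    @property
    def perimeter(self) -> float:
        if self.kind == "square":
            return 4.0 * self.width
        if self.kind == "rectangle":
            return 2.0 * (self.width + (self.height or self.width))
        return 2.0 * math.pi * self.width


@dataclass
class WallpaperSpec:
    """Recipe for one wallpaper image."""

    tile: int
    figures_per_tile: list[FigureSpec]
    seed: int = 0
    width: int = WALLPAPER_WIDTH

    def __post_init__(self) -> None:
        if self.width % self.tile:
            raise GenerationError(
                f"tile ({self.tile}) must divide width ({self.width})"
            )

    @property
    def n_tiles(self) -> int:
        return (self.width // self.tile) ** 2


@dataclass(frozen=True)
class TheoryValues:
    """Exact theoretical read-outs of a wallpaper."""

    sum_area: float  # px^2, all figures of the whole image
    sum_perimeter: float  # px
    width: int

    @property
    def vv_sep(self) -> float:
        return (self.width**2 - self.sum_area) / self.width**2

    @property
    def lm_px(self) -> float:
        """4 (1 - VVsep) W^2 / sum_perimeter = 4A/P; 0 when figure-free."""
        if self.sum_perimeter == 0:
            return 0.0
        return 4.0 * self.sum_area / self.sum_perimeter

    def lm_um(self, scale: float = DEFAULT_SCALE_UM_PER_PX) -> float:
        return self.lm_px * scale

    def to_dict(self) -> dict:
        return {
            "sum_area_px2": self.sum_area,
            "sum_perimeter_px": self.sum_perimeter,
            "width_px": self.width,
            "vv_sep_theory": self.vv_sep,
            "lm_theory_px": self.lm_px,
        }


def _place_in_tile(
    figures: list[FigureSpec], tile: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random non-overlapping placements (x, y of bbox corner) inside one
    tile.

    Each figure is assigned its own cell of a g x g grid (g^2 >= n) and
    jittered uniformly within the cell, so placements are random while
    non-overlap and tile containment hold by construction. A figure whose
    bounding box exceeds its cell makes the spec infeasible.
    """
    n = len(figures)
    if n == 0:
        return []
    g = math.ceil(math.sqrt(n))
    cell = tile // g
    order = rng.permutation(g * g)[:n]  # which cell each figure occupies
    placements: list[tuple[int, int]] = []
    for fig, cell_idx in zip(figures, order):
        w, h = fig.bbox
        if w > cell or h > cell:
            raise GenerationError(
                f"figure {fig} (bbox {w}x{h}) does not fit a "
                f"{cell}x{cell} cell of the {tile}px tile"
            )
        cx = (int(cell_idx) % g) * cell
        cy = (int(cell_idx) // g) * cell
        jx = int(rng.integers(0, cell - w + 1))
        jy = int(rng.integers(0, cell - h + 1))
        placements.append((cx + jx, cy + jy))
    return placements


def _draw_figure(
    canvas: np.ndarray, fig: FigureSpec, x: int, y: int
) -> None:
    w, h = fig.bbox
    if fig.kind == "circle":
        r = fig.width
        rr, cc = draw_disk((y + r, x + r), r + 0.5, shape=canvas.shape)
        canvas[rr, cc] = True
    else:
        canvas[y : y + h, x : x + w] = True


def make_wallpaper(spec: WallpaperSpec) -> tuple[np.ndarray, TheoryValues]:
    """Render a wallpaper and its exact theory values.

    Returns (image, theory) where image is a boolean array with True =
    white = airspace figure. Deterministic given the spec's seed. The
    white pixel count equals sum_area exactly when the spec contains only
    squares and rectangles (drawn without anti-aliasing).
    """
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((spec.width, spec.width), dtype=bool)
    per_side = spec.width // spec.tile
    for ty in range(per_side):
        for tx in range(per_side):
            placements = _place_in_tile(spec.figures_per_tile, spec.tile, rng)
            for fig, (x, y) in zip(spec.figures_per_tile, placements):
                _draw_figure(img, fig, tx * spec.tile + x, ty * spec.tile + y)
    n = spec.n_tiles
    theory = TheoryValues(
        sum_area=n * sum(f.area for f in spec.figures_per_tile),
        sum_perimeter=n * sum(f.perimeter for f in spec.figures_per_tile),
        width=spec.width,
    )
    return img, theory


def save_wallpaper(
    img: np.ndarray,
    theory: TheoryValues,
    spec: WallpaperSpec,
    path: str | Path,
) -> None:
    """Write a wallpaper as PNG plus a JSON sidecar with spec, seed and
    theory values."""
    path = Path(path)
    Image.fromarray(img.astype(np.uint8) * 255).save(path)
    sidecar = {
        "spec": {
            "width": spec.width,
            "tile": spec.tile,
            "seed": spec.seed,
            "figures_per_tile": [
                {"kind": f.kind, "width": f.width, "height": f.height}
                for f in spec.figures_per_tile
            ],
        },
        "theory": theory.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def wallpaper_series(
    n_images: int = 11,
    vv_range: tuple[float, float] = (0.3, 0.9),
    tile: int = 340,
    seed: int = 0,
) -> list[tuple[WallpaperSpec, TheoryValues]]:
    """Specs for a validation series spanning a range of densities.

    Image j targets a septal density evenly spaced across ``vv_range``
    (airspace fraction 1 - VVsep). Each tile holds four figures — two
    squares and two rectangles — in a 2x2 cell grid, sized so their total
    area hits the target fraction; the realized (integer-dimension)
    figures define the exact theory values.
    """
    if n_images < 1:
        raise GenerationError("n_images must be >= 1")
    cell = tile // 2
    vv_targets = np.linspace(vv_range[0], vv_range[1], n_images)
    out = []
    for j, vv in enumerate(vv_targets):
        air_frac = 1.0 - float(vv)
        area_per_fig = air_frac * tile * tile / 4.0
        side = math.sqrt(area_per_fig)
        figures: list[FigureSpec] = []
        for i in range(4):
            if i % 2 == 0:
                a = max(2, round(side))
                if a > cell:
                    raise GenerationError("square exceeds cell size")
                figures.append(FigureSpec("square", a))
            else:
                aspect = 1.3 if i == 1 else 1.15
                w = min(cell, max(2, round(side * math.sqrt(aspect))))
                h = max(2, round(area_per_fig / w))
                if h > cell:
                    raise GenerationError("rectangle exceeds cell size")
                figures.append(FigureSpec("rectangle", w, h))
        spec = WallpaperSpec(
            tile=tile, figures_per_tile=figures, seed=seed * 1009 + j
        )
        _, theory = make_wallpaper_theory(spec)
        out.append((spec, theory))
    return out


def make_wallpaper_theory(spec: WallpaperSpec) -> tuple[None, TheoryValues]:
    """Theory values of a spec without rendering the raster."""
    n = spec.n_tiles
    return None, TheoryValues(
        sum_area=n * sum(f.area for f in spec.figures_per_tile),
        sum_perimeter=n * sum(f.perimeter for f in spec.figures_per_tile),
        width=spec.width,
    )


def sample_fields(
    image: np.ndarray,
    n: int,
    seed: int = 0,
    size: int = FIELD_SIZE,
    tissue_constraint: np.ndarray | None = None,
    scale: float = DEFAULT_SCALE_UM_PER_PX,
    max_tries_per_field: int = 1000,
) -> list[FieldImage]:
    """Randomly extract n (possibly overlapping) size x size fields.

    Top-left coordinates are drawn uniformly with replacement from the
    valid range. With a ``tissue_constraint`` mask (same shape as image),
    a candidate is accepted only when the field center lies in tissue —
    rejection sampling with a bounded retry budget. Deterministic given
    the seed.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < size or w < size:
        raise SamplingError(
            f"image {w}x{h} smaller than the field size {size}"
        )
    if n < 1:
        raise SamplingError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fields: list[FieldImage] = []
    for _ in range(n):
        for _try in range(max_tries_per_field):
            x = int(rng.integers(0, w - size + 1))
            y = int(rng.integers(0, h - size + 1))
            if tissue_constraint is not None:
                cy, cx = y + size // 2, x + size // 2
                if not tissue_constraint[cy, cx]:
                    continue
            break
        else:
            raise SamplingError(
                f"no field satisfying the tissue constraint after "
                f"{max_tries_per_field} tries"
            )
        crop = image[y : y + size, x : x + size]
        if crop.dtype == bool:
            px = crop.astype(np.uint8) * 255
        else:
            px = np.clip(crop, 0, 255).astype(np.uint8)
        fields.append(
            FieldImage(
                pixels=px, scale_um_per_px=scale, source_id=f"x{x}_y{y}"
            )
        )
    return fields


@dataclass
class PhantomParams:
    """Knobs of the histology phantom generator.

    Defaults emulate neonatal distal lung at 0.735 um/px: ~60 airspaces
    per 680px field (alveolar diameter ~65 um), septa ~5 um thick
    (7 px), a couple of large vessel-like profiles and a handful of
    free exudate particles in the airspaces.
    """

    size: int = FIELD_SIZE
    airspace_count: int = 60
    wall_thickness_px: int = 7
    vessel_count: int = 2
    vessel_radius_px: tuple[int, int] = (30, 50)
    exudate_count: int = 5
    exudate_area_px: tuple[int, int] = (100, 900)
    septa_mean: float = 70.0
    exudate_mean: float = 90.0
    vessel_mean: float = 70.0
    air_mean: float = 220.0
    noise_sd: float = 8.0
    seed: int = 0


@dataclass
class HistologyPhantom:
    """A generated field with disjoint per-phase truth masks."""

    image: FieldImage
    truth_septa: np.ndarray
    truth_vessels: np.ndarray
    truth_exudates: np.ndarray
    params: PhantomParams

    @property
    def truth_tissue(self) -> np.ndarray:
        """Union of all dark (tissue-like) phases."""
        return self.truth_septa | self.truth_vessels | self.truth_exudates


def _disk_area(r: int) -> int:
    """Exact pixel count of the closed lattice disk of radius r."""
    d = np.arange(-r, r + 1)
    return int(((d[:, None] ** 2 + d[None, :] ** 2) <= r * r).sum())


def _disk_radius_for_area_range(
    area_range: tuple[int, int], target: int
) -> int:
    """Radius whose exact lattice-disk area lies inside area_range,
    as close to target as possible."""
    lo, hi = area_range
    candidates = [r for r in range(1, 64) if lo <= _disk_area(r) <= hi]
    if not candidates:
        raise GenerationError(
            f"no lattice disk has an area inside {area_range}"
        )
    return min(candidates, key=lambda r: abs(_disk_area(r) - target))


def make_histology_phantom(params: PhantomParams | None = None) -> HistologyPhantom:
    """Generate a histology-like phantom field.

    The septal network is the dilated boundary set of a random nearest-
    seed (Voronoi) partition of the field — closed polygonal airspaces,
    as in distal lung. Vessel-like disks are stamped over it; exudate-like
    disks are dropped into airspace interiors, away from any septum, so
    they are unconnected particles the automatic filter should remove.
    Deterministic given params.seed.
    """
    p = params or PhantomParams()
    rng = np.random.default_rng(p.seed)
    size = p.size

    # Voronoi partition -> septal ridges
    seeds = rng.uniform(0, size, size=(p.airspace_count, 2))
    yy, xx = np.mgrid[0:size, 0:size]
    _, labels = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
    labels = labels.reshape(size, size)
    ridge = np.zeros((size, size), dtype=bool)
    ridge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    ridge[:-1, :] |= labels[:-1, :] != labels[1:, :]
    septa = ndimage.binary_dilation(
        ridge, structure=disk_footprint(max(1, p.wall_thickness_px // 2))
    )

    vessels = np.zeros_like(septa)
    for _ in range(p.vessel_count):
        r = int(rng.integers(p.vessel_radius_px[0], p.vessel_radius_px[1] + 1))
        cy = int(rng.integers(r + 2, size - r - 2))
        cx = int(rng.integers(r + 2, size - r - 2))
        rr, cc = draw_disk((cy, cx), r, shape=septa.shape)
        vessels[rr, cc] = True
    septa &= ~vessels

    # exudates: unconnected particles strictly inside airspaces
    exudates = np.zeros_like(septa)
    blocked = septa | vessels
    margin_map = ndimage.distance_transform_edt(~blocked)
    dd = np.arange(-63, 64)
    dist2 = dd[:, None] ** 2 + dd[None, :] ** 2
    for _ in range(p.exudate_count):
        area = int(rng.integers(p.exudate_area_px[0], p.exudate_area_px[1] + 1))
        r = _disk_radius_for_area_range(p.exudate_area_px, area)
        offs = np.argwhere(dist2 <= r * r) - 63
        placed = False
        for _try in range(2000):
            cy = int(rng.integers(r + 2, size - r - 2))
            cx = int(rng.integers(r + 2, size - r - 2))
            if margin_map[cy, cx] <= r + 2:
                continue
            rr, cc = offs[:, 0] + cy, offs[:, 1] + cx
            if exudates[rr, cc].any():
                continue
            stamp = np.zeros_like(exudates)
            stamp[rr, cc] = True
            if (ndimage.binary_dilation(stamp, structure=np.ones((3, 3)))
                    & (blocked | exudates)).any():
                continue
            exudates |= stamp
            placed = True
            break
        if not placed:
            raise GenerationError(
                "could not place an exudate clear of the septal network"
            )

    img = np.full((size, size), p.air_mean, dtype=float)
    img[septa] = p.septa_mean
    img[vessels] = p.vessel_mean
    img[exudates] = p.exudate_mean
    if p.noise_sd > 0:
        img += rng.normal(0.0, p.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return HistologyPhantom(
        image=FieldImage(pixels=pixels, source_id=f"phantom_seed{p.seed}"),
        truth_septa=septa,
        truth_vessels=vessels,
        truth_exudates=exudates,
        params=p,
    )
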