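"""The stereological test system and the per-field counts.

The test system lives on the central 567x567 px counting frame of the
standardized 680x680 field: 8 horizontal and 8 vertical test lines of
567 px, one line centered in each of 8 equal strips, whose 64 crossings
form the point grid. The test-line length associated with each point is
d = 104 um (141.75 px at 0.735 um/px), the constant that links point
counts to line length in the intercept estimator.

Per field, four counts are taken:

- ``p_nonpar`` — grid points on manually selected non-parenchymal tissue;
- ``p_ref``   — the remaining reference points (64 − p_nonpar);
- ``p_sep``   — reference points whose pixel is septal tissue in the
  clean mask;
- ``i_h``/``i_v`` — intersections of the air-tissue interface with the
  horizontal / vertical test lines, where one maximal contiguous run of
  edge pixels along a line counts as one intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StageError
from .geometry import points_in_any_polygon, rasterize_polygons
from .ingest import (
    DEFAULT_SCALE_UM_PER_PX,
    FIELD_SIZE,
    FieldImage,
    RoiSet,
    apply_threshold,
)
from .segmentation import (
    BinaryMask,
    EdgeMask,
    apply_manual_selections,
    clean_mask,
    extract_edges,
    remove_auto_exudates,
)

#: Counting frame edge length (pixels) and its offset in the field.
FRAME_SIZE = 567
FRAME_ORIGIN = (FIELD_SIZE - FRAME_SIZE) // 2  # 56
#: Unit test-line length per grid point at the default line density (um).
DEFAULT_D_UM = 104.0


@dataclass(frozen=True)
class TestSystem:
    """Quadratic point/line test system on the central counting frame.

    ``density`` multiplies the number of lines per orientation (8 at
    density 1); the grid points are the line crossings, so a density-k
    system has (8k)^2 points and d scales as 104/k um.
    """

    h_rows: np.ndarray  # row coordinate of each horizontal line
    v_cols: np.ndarray  # column coordinate of each vertical line
    frame_origin: int
    frame_size: int
    d_um: float
    scale_um_per_px: float
    density: int = 1

    @property
    def n_lines(self) -> int:
        return len(self.h_rows)

    @property
    def n_points(self) -> int:
        return self.n_lines**2

    @property
    def d_px(self) -> float:
        """Test-line length per point, in pixels: 2 * frame / n_lines."""
        return 2.0 * self.frame_size / self.n_lines

    @property
    def total_line_length_px(self) -> int:
        return 2 * self.n_lines * self.frame_size

    @property
    def grid_points(self) -> np.ndarray:
        """All line crossings as an (n_points, 2) array of (x, y)."""
        cc, rr = np.meshgrid(self.v_cols, self.h_rows)
        return np.column_stack([cc.ravel(), rr.ravel()])

    @property
    def frame_span(self) -> tuple[int, int]:
        """Half-open pixel range [start, stop) covered by the lines."""
        return self.frame_origin, self.frame_origin + self.frame_size


def build_test_system(
    scale: float = DEFAULT_SCALE_UM_PER_PX,
    density: int = 1,
    d_um: float | None = None,
) -> TestSystem:
    """Construct the test system.

    Line k (k = 0..n-1) is placed at frame_origin + round((k+0.5)*567/n),
    i.e. centered in each of n equal strips, giving a symmetric grid.
    Any fixed placement is stereologically valid for batch comparison;
    this one is frozen so counts are reproducible.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if density < 1:
        raise ValueError("density must be >= 1")
    n = 8 * density
    pos = FRAME_ORIGIN + np.round((np.arange(n) + 0.5) * FRAME_SIZE / n).astype(
        int
    )
    if d_um is None:
        d_um = DEFAULT_D_UM / density
    return TestSystem(
        h_rows=pos,
        v_cols=pos.copy(),
        frame_origin=FRAME_ORIGIN,
        frame_size=FRAME_SIZE,
        d_um=float(d_um),
        scale_um_per_px=float(scale),
        density=density,
    )


@dataclass(frozen=True)
class FieldCounts:
    """The stereology counts of one field."""

    p_nonpar: int
    p_ref: int
    p_sep: int
    i_h: int
    i_v: int
    source_id: str = ""
    threshold: int | None = None

    @property
    def i_total(self) -> int:
        return self.i_h + self.i_v

    def __post_init__(self) -> None:
        if min(self.p_nonpar, self.p_ref, self.p_sep, self.i_h, self.i_v) < 0:
            raise ValueError("counts must be non-negative")
        if self.p_sep > self.p_ref:
            raise ValueError("p_sep cannot exceed p_ref")


def count_pref(rois: RoiSet, ts: TestSystem) -> tuple[int, int]:
    """Points on non-parenchyma vs reference points.

    A grid point on the boundary of a non-parenchyma polygon counts as
    excluded. Returns (p_nonpar, p_ref) with p_nonpar + p_ref = n_points.
    """
    pts = ts.grid_points
    hit = points_in_any_polygon(pts[:, 0], pts[:, 1], rois.nonpar_polygons())
    p_nonpar = int(hit.sum())
    return p_nonpar, ts.n_points - p_nonpar


def count_psep(mask: BinaryMask, rois: RoiSet, ts: TestSystem) -> int:
    """Reference grid points whose pixel is septal tissue."""
    mask._require_stage("clean")
    pts = ts.grid_points
    on_tissue = mask.tissue[pts[:, 1], pts[:, 0]]
    excluded = points_in_any_polygon(
        pts[:, 0], pts[:, 1], rois.nonpar_polygons()
    )
    return int(np.sum(on_tissue & ~excluded))


def _runs(line: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans of the maximal True runs of a 1-D
    boolean array."""
    padded = np.concatenate([[False], line, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def count_intersections(
    edge: EdgeMask, rois: RoiSet, ts: TestSystem
) -> tuple[int, int, int]:
    """Count intersections of the edge image with the test lines.

    For each orientation the intersection image is the AND of the edge
    image and the line pixels; each maximal contiguous run of such pixels
    along a line counts once (this mirrors counting "particles" on the
    AND image). Runs lying entirely inside a non-parenchyma region are
    excluded — those interfaces are not part of the reference space.
    """
    lo, hi = ts.frame_span
    nonpar = None
    if rois.non_parenchyma:
        nonpar = rasterize_polygons(rois.nonpar_polygons(), edge.edge.shape)

    def count_line(vals: np.ndarray, excl: np.ndarray | None) -> int:
        n = 0
        for start, stop in _runs(vals):
            if excl is not None and excl[start:stop].all():
                continue
            n += 1
        return n

    i_h = 0
    for r in ts.h_rows:
        i_h += count_line(
            edge.edge[r, lo:hi],
            None if nonpar is None else nonpar[r, lo:hi],
        )
    i_v = 0
    for c in ts.v_cols:
        i_v += count_line(
            edge.edge[lo:hi, c],
            None if nonpar is None else nonpar[lo:hi, c],
        )
    return i_h, i_v, i_h + i_v


def count_mask(
    mask: BinaryMask,
    rois: RoiSet,
    ts: TestSystem,
    source_id: str = "",
    threshold: int | None = None,
) -> FieldCounts:
    """Run the three counters on an already-clean mask."""
    mask._require_stage("clean")
    p_nonpar, p_ref = count_pref(rois, ts)
    p_sep = count_psep(mask, rois, ts)
    i_h, i_v, _ = count_intersections(extract_edges(mask), rois, ts)
    return FieldCounts(
        p_nonpar=p_nonpar,
        p_ref=p_ref,
        p_sep=p_sep,
        i_h=i_h,
        i_v=i_v,
        source_id=source_id,
        threshold=threshold,
    )


def count_field(
    img: FieldImage,
    rois: RoiSet,
    t: int,
    ts: TestSystem,
) -> FieldCounts:
    """Full pipeline on one grayscale field.

    threshold -> automatic exudate removal -> manual selections ->
    mask cleaning -> edge extraction -> point and intersection counting.
    Deterministic: identical inputs give identical counts.
    """
    raw = apply_threshold(img, t)
    filtered, _ = remove_auto_exudates(raw)
    filtered = apply_manual_selections(filtered, rois)
    clean = clean_mask(filtered)
    return count_mask(clean, rois, ts, source_id=img.source_id, threshold=t)


def count_binary_field(
    img: FieldImage,
    ts: TestSystem,
    rois: RoiSet | None = None,
    air_is_white: bool = True,
) -> FieldCounts:
    """Counting variant for binary synthetic fields.

    Skips the steps that turn a color image into a cleaned mask: the
    raster is read directly as tissue (black) vs air (white figures) and
    counted as a clean mask.
    """
    from .segmentation import as_clean

    if rois is None:
        rois = RoiSet()
    tissue = img.pixels < 128 if air_is_white else img.pixels >= 128
    return count_mask(as_clean(tissue), rois, ts, source_id=img.source_id)
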