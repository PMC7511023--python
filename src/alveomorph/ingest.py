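"""Field ingestion: load raster fields and ROI files, standardize geometry
and intensity, and threshold to a raw tissue mask.

A *field* is a 500x500 um crop of an H&E-stained lung section. Whatever its
native pixel count, it is standardized to a 680x680 8-bit grayscale raster
at 0.735 um/px so the fixed test system (64 points, 16 test lines) applies
unchanged to every image of a batch.

ROI files replace the interactive freehand selections of the original
workflow: a JSON document with two named polygon lists, ``non_parenchyma``
(conducting airways, arteries, veins, pleura) and ``manual_exudates``
(airspace exudates too large or too connected for the automatic filter).
Coordinates are (x, y) pixels of the standardized field.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import Polygon
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .errors import IngestError, RoiParseError

#: Standardized field edge length in pixels.
FIELD_SIZE = 680
#: Physical scale of the standardized field (um per pixel). 680 px at this
#: scale is 499.8 um, accepted as the nominal 500 um field.
DEFAULT_SCALE_UM_PER_PX = 0.735


@dataclass
class FieldImage:
    """A standardized 680x680 8-bit grayscale lung field.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (680, 680)
        Intensities, 0 = black. H&E tissue is darker than airspace.
    scale_um_per_px : float
        Physical pixel size; 0.735 um/px after standardization.
    source_id : str
        Provenance (file name, optionally sampling coordinates).
    """

    pixels: np.ndarray
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (FIELD_SIZE, FIELD_SIZE):
            raise IngestError(
                f"FieldImage must be {FIELD_SIZE}x{FIELD_SIZE}, "
                f"got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise IngestError("FieldImage pixels must be uint8")
        if self.scale_um_per_px <= 0:
            raise IngestError("scale_um_per_px must be positive")


@dataclass
class RoiSet:
    """Manual region selections for one field.

    Two polygon lists in standardized-field pixel coordinates: regions of
    non-parenchymal tissue (excluded from the reference space) and manually
    identified exudates (blanked from the septal mask). Spatial overlap
    between the lists is resolved in favor of non-parenchyma.
    """

    non_parenchyma: list[np.ndarray] = field(default_factory=list)
    manual_exudates: list[np.ndarray] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.non_parenchyma and not self.manual_exudates

    def nonpar_polygons(self) -> list[Polygon]:
        return [Polygon(p) for p in self.non_parenchyma]

    def exudate_polygons(self) -> list[Polygon]:
        return [Polygon(p) for p in self.manual_exudates]

    def to_json(self) -> str:
        return json.dumps(
            {
                "non_parenchyma": [p.tolist() for p in self.non_parenchyma],
                "manual_exudates": [p.tolist() for p in self.manual_exudates],
            }
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _validate_polygon(verts, role: str, index: int) -> np.ndarray:
    arr = np.asarray(verts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise RoiParseError(
            f"polygon {index} in list '{role}' is degenerate: "
            f"need >= 3 (x, y) vertices, got shape {arr.shape}"
        )
    # clip to the standardized field
    return np.clip(arr, 0.0, float(FIELD_SIZE))


def load_roiset(path: str | Path | None) -> RoiSet:
    """Parse a ROI JSON file into a :class:`RoiSet`.

    An absent path (``None`` or a non-existent file) yields an empty set,
    matching fields that need no manual exclusion. Vertices outside the
    680x680 field are clipped onto its border.
    """
    if path is None:
        return RoiSet()
    path = Path(path)
    if not path.exists():
        return RoiSet()
    text = path.read_text().strip()
    if not text:
        return RoiSet()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RoiParseError(f"malformed ROI JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise RoiParseError(f"ROI file {path} must contain a JSON object")
    out = RoiSet()
    for role, target in (
        ("non_parenchyma", out.non_parenchyma),
        ("manual_exudates", out.manual_exudates),
    ):
        for i, verts in enumerate(doc.get(role, [])):
            target.append(_validate_polygon(verts, role, i))
    return out


def roiset_from_masks(
    non_parenchyma: np.ndarray | None = None,
    manual_exudates: np.ndarray | None = None,
) -> RoiSet:
    """Build a RoiSet from binary PNG-style masks (non-zero = selected).

    Alternative ROI encoding: each mask is polygonized by contour tracing,
    so downstream point-in-polygon tests see (approximately) the same
    region the mask marks.
    """
    out = RoiSet()
    for mask, target, role in (
        (non_parenchyma, out.non_parenchyma, "non_parenchyma"),
        (manual_exudates, out.manual_exudates, "manual_exudates"),
    ):
        if mask is None:
            continue
        m = np.asarray(mask) != 0
        if m.shape != (FIELD_SIZE, FIELD_SIZE):
            raise RoiParseError(
                f"ROI mask for '{role}' must be {FIELD_SIZE}x{FIELD_SIZE}"
            )
        padded = np.pad(m.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            verts = contour[:, ::-1] - 1.0  # (row, col) -> (x, y), unpad
            if len(verts) >= 3:
                target.append(_validate_polygon(verts, role, len(target)))
    return out


def load_field(path: str | Path, scale: float | None = None) -> FieldImage:
    """Load a PNG lung field and standardize it to 680x680 8-bit grayscale.

    RGB input is collapsed with an unweighted channel mean (the common
    macro default); resizing is bilinear. The physical scale is fixed at
    0.735 um/px unless overridden.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise IngestError(f"cannot read image {path}: {exc}") from exc
    return standardize_field(
        arr,
        scale=scale,
        source_id=path.name,
    )


def standardize_field(
    arr: np.ndarray,
    scale: float | None = None,
    source_id: str = "",
    rgb_weights: tuple[float, float, float] | None = None,
) -> FieldImage:
    """Standardize an in-memory raster to a :class:`FieldImage`.

    Steps: drop alpha, collapse RGB to one channel (unweighted mean by
    default, or the given luminance weights), bilinear-resize to 680x680,
    round to uint8. Already-standardized input passes through unchanged.
    """
    arr = np.asarray(arr)
    if arr.size == 0:
        raise IngestError(f"zero-sized image: {source_id!r}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            if rgb_weights is None:
                gray = arr.astype(float).mean(axis=2)
            else:
                w = np.asarray(rgb_weights, dtype=float)
                gray = arr.astype(float) @ (w / w.sum())
        elif arr.shape[2] == 1:
            gray = arr[:, :, 0].astype(float)
        else:
            raise IngestError(f"unsupported channel count {arr.shape[2]}")
    elif arr.ndim == 2:
        gray = arr.astype(float)
    else:
        raise IngestError(f"unsupported image dimensionality {arr.ndim}")
    if arr.dtype == bool:
        gray = gray * 255.0
    if gray.shape != (FIELD_SIZE, FIELD_SIZE):
        gray = resize(
            gray,
            (FIELD_SIZE, FIELD_SIZE),
            order=1,  # bilinear
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    pixels = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return FieldImage(
        pixels=pixels,
        scale_um_per_px=scale if scale is not None else DEFAULT_SCALE_UM_PER_PX,
        source_id=source_id,
    )


def suggest_threshold(img: FieldImage) -> int:
    """Suggest a tissue/air intensity threshold via Otsu's method.

    The batch contract is one threshold per batch, chosen on its first
    image; this provides a non-interactive starting value the user may
    override in the batch config. A constant image has no separable
    classes: returns 0 and emits a warning.
    """
    px = img.pixels
    if px.min() == px.max():
        warnings.warn(
            "constant image: no tissue/air separation, threshold set to 0",
            stacklevel=2,
        )
        return 0
    return int(threshold_otsu(px))


def apply_threshold(img: FieldImage, t: int):
    """Binarize a field: tissue = intensity <= t (H&E tissue is darker
    than airspace). Returns a raw-stage BinaryMask."""
    from .segmentation import BinaryMask  # local import to avoid a cycle

    if not 0 <= t <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    return BinaryMask(tissue=img.pixels <= t, stage="raw")
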