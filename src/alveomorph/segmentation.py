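"""Mask segmentation: from the raw thresholded tissue mask to a cleaned
septal mask and its edge image.

The raw mask still contains alveolar exudates (cellular debris that stains
like tissue) and whatever non-parenchymal structures the threshold caught.
Three steps remove them:

1. ``remove_auto_exudates`` — drop small unconnected tissue particles
   (1-1000 px, not touching the image border): free-floating exudates.
2. ``apply_manual_selections`` — blank manually selected regions (large or
   septum-touching exudates, and all non-parenchymal tissue) to air.
3. ``clean_mask`` — fill small air holes inside septa (1-200 px), suppress
   single-pixel outliers with a local median rule, and smooth with one
   morphological closing.

``extract_edges`` then takes the clean mask to a one-pixel-thick inner
tissue boundary — the air-tissue interface the intersection counter reads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import StageError
from .geometry import rasterize_polygons
from .ingest import RoiSet

_STAGES = ("raw", "exudate_filtered", "clean")
_SQUARE3 = np.ones((3, 3), dtype=bool)
_CROSS3 = ndimage.generate_binary_structure(2, 1)

#: Automatic exudate filter: particle area bounds in pixels.
EXUDATE_AREA_MAX = 1000
#: Hole filling: air particles of up to this area inside tissue are filled.
HOLE_AREA_MAX = 200


@dataclass
class BinaryMask:
    """A 680x680 tissue/air mask at a known pipeline stage."""

    tissue: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue, dtype=bool)
        if self.tissue.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"expected a {stage!r}-stage mask, got {self.stage!r}"
            )


@dataclass
class EdgeMask:
    """One-pixel-thick air-tissue interface of a clean mask (tissue side)."""

    edge: np.ndarray

    def __post_init__(self) -> None:
        self.edge = np.asarray(self.edge, dtype=bool)


@dataclass(frozen=True)
class RemovedComponent:
    """Descriptor of an automatically removed exudate particle (for the
    QC overlay and batch log)."""

    area: int
    centroid: tuple[float, float]  # (row, col)


def remove_auto_exudates(
    mask: BinaryMask, area_max: int = EXUDATE_AREA_MAX
) -> tuple[BinaryMask, list[RemovedComponent]]:
    """Remove unconnected tissue particles of 1..area_max pixels that do
    not touch the image border (automatic exudate detection).

    Components are 8-connected. Larger particles, and particles in contact
    with the border (possibly truncated septa), are left for manual
    selection.
    """
    mask._require_stage("raw")
    labels, n = ndimage.label(mask.tissue, structure=_SQUARE3)
    out = mask.tissue.copy()
    removed: list[RemovedComponent] = []
    if n:
        border_labels = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        border = set(border_labels.tolist()) - {0}
        areas = ndimage.sum_labels(
            np.ones_like(labels), labels, index=np.arange(1, n + 1)
        ).astype(int)
        kill = [
            lab
            for lab, area in zip(range(1, n + 1), areas)
            if area <= area_max and lab not in border
        ]
        if kill:
            centroids = ndimage.center_of_mass(mask.tissue, labels, kill)
            for lab, com in zip(kill, centroids):
                removed.append(
                    RemovedComponent(
                        area=int(areas[lab - 1]),
                        centroid=(float(com[0]), float(com[1])),
                    )
                )
            out[np.isin(labels, kill)] = False
    return BinaryMask(tissue=out, stage="exudate_filtered"), removed


def apply_manual_selections(mask: BinaryMask, rois: RoiSet) -> BinaryMask:
    """Blank all manually selected regions to air.

    Both manual exudates and non-parenchymal regions are set to air so
    that neither contributes septal points or edge intersections. The
    union is taken, so overlapping selections are order-independent.
    """
    mask._require_stage("exudate_filtered")
    if rois.is_empty():
        return replace(mask, tissue=mask.tissue.copy())
    blank = rasterize_polygons(
        rois.nonpar_polygons() + rois.exudate_polygons(), mask.tissue.shape
    )
    return BinaryMask(tissue=mask.tissue & ~blank, stage="exudate_filtered")


def clean_mask(
    mask: BinaryMask,
    hole_area_max: int = HOLE_AREA_MAX,
    outlier_radius: int = 2,
    closing_iterations: int = 1,
) -> BinaryMask:
    """Clean the exudate-filtered mask: hole filling, outlier removal,
    morphological closing.

    (a) Air components of 1..hole_area_max px fully enclosed by tissue
        (4-connected, no border contact) are filled to tissue.
    (b) Outlier removal: each pixel is replaced by the majority value in a
        disk of ``outlier_radius`` — i.e. a binary median filter — which
        suppresses salt-and-pepper noise without eroding septa of realistic
        thickness (>= 2 px at radius 2).
    (c) One dilate-erode sequence (closing) with a 3x3 square element;
        erosion treats the outside of the image as tissue so border septa
        are not shaved.
    """
    mask._require_stage("exudate_filtered")
    tissue = mask.tissue.copy()

    # (a) fill small enclosed air holes
    air_labels, n_air = ndimage.label(~tissue, structure=_CROSS3)
    if n_air:
        border = set(
            np.unique(
                np.concatenate(
                    [
                        air_labels[0, :],
                        air_labels[-1, :],
                        air_labels[:, 0],
                        air_labels[:, -1],
                    ]
                )
            ).tolist()
        ) - {0}
        areas = ndimage.sum_labels(
            np.ones_like(air_labels),
            air_labels,
            index=np.arange(1, n_air + 1),
        ).astype(int)
        fill = [
            lab
            for lab, area in zip(range(1, n_air + 1), areas)
            if area <= hole_area_max and lab not in border
        ]
        if fill:
            tissue[np.isin(air_labels, fill)] = True

    # (b) binary median (majority) filter
    if outlier_radius > 0:
        footprint = disk(outlier_radius)
        votes = ndimage.convolve(
            tissue.astype(np.int32), footprint.astype(np.int32), mode="nearest"
        )
        tissue = votes * 2 > int(footprint.sum())

    # (c) closing
    for _ in range(closing_iterations):
        dilated = ndimage.binary_dilation(tissue, structure=_SQUARE3)
        tissue = ndimage.binary_erosion(
            dilated, structure=_SQUARE3, border_value=1
        )

    return BinaryMask(tissue=tissue, stage="clean")


def extract_edges(mask: BinaryMask) -> EdgeMask:
    """Inner tissue boundary of the clean mask.

    Edge pixels are tissue pixels with at least one 4-neighbor of air:
    the mask minus its erosion by the 3x3 cross. The outside of the image
    is treated as tissue, so the image border itself is never an edge and
    an all-tissue mask has no edges.
    """
    mask._require_stage("clean")
    eroded = ndimage.binary_erosion(
        mask.tissue, structure=_CROSS3, border_value=1
    )
    return EdgeMask(edge=mask.tissue & ~eroded)


def as_clean(tissue: np.ndarray) -> BinaryMask:
    """Wrap an already-binary tissue raster as a clean-stage mask.

    Used for binary synthetic images, where the color-to-clean-mask steps
    of the pipeline are skipped and counting runs on the raster as-is.
    """
    return BinaryMask(tissue=np.asarray(tissue, dtype=bool), stage="clean")
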