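"""Batch orchestration: folders of fields in, CSVs and QC overlays out,
plus the built-in synthetic validation experiment.

The batch contract mirrors routine use: one intensity threshold per batch
(set on the first image, or an explicit value), ROI files matched to
fields by filename stem (``field.png`` <-> ``field.rois.json``), one CSV
row per field and one summary row per subject.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import stereology
from .agreement import AgreementResult, method_agreement
from .counting import (
    DEFAULT_D_UM,
    TestSystem,
    build_test_system,
    count_binary_field,
    count_field,
    FieldCounts,
)
from .errors import UsageError
from .ingest import (
    DEFAULT_SCALE_UM_PER_PX,
    FieldImage,
    RoiSet,
    apply_threshold,
    load_field,
    load_roiset,
    suggest_threshold,
)
from .segmentation import (
    apply_manual_selections,
    clean_mask,
    extract_edges,
    remove_auto_exudates,
)
from .synthetic import sample_fields, make_wallpaper, wallpaper_series

logger = logging.getLogger("alveomorph.batch")

#: Frozen per-field CSV header.
FIELD_CSV_COLUMNS = [
    "source_id",
    "subject_id",
    "p_nonpar",
    "p_ref",
    "p_sep",
    "i_h",
    "i_v",
    "i_total",
    "threshold",
]
#: Frozen per-subject CSV header.
SUBJECT_CSV_COLUMNS = [
    "subject_id",
    "n_fields",
    "sum_p_nonpar",
    "sum_p_ref",
    "sum_p_sep",
    "sum_i",
    "vv_sep",
    "lm_um",
    "lmw_um",
    "sv_air_per_um",
]


@dataclass
class BatchConfig:
    """Configuration of one counting batch."""

    input_dir: str | Path
    output_dir: str | Path
    roi_dir: str | Path | None = None
    threshold: int | str = "otsu-first"  # one threshold per batch
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    d_um: float = DEFAULT_D_UM
    qc: bool = False
    subject_pattern: str = r"^([^_]+)"  # first filename-stem token
    roi_suffix: str = ".rois.json"


@dataclass
class BatchReport:
    """Outputs of :func:`run_batch`."""

    fields: pd.DataFrame
    subjects: pd.DataFrame
    threshold: int
    field_csv: Path
    subject_csv: Path
    failures: list[str] = dc_field(default_factory=list)


def _subject_of(stem: str, pattern: str) -> str:
    m = re.search(pattern, stem)
    return m.group(1) if m else stem


def qc_overlay(
    img: FieldImage, clean_tissue: np.ndarray, ts: TestSystem
) -> np.ndarray:
    """RGB overlay: clean-mask edge (red) and test system (green) over
    the original field — the visual check of segmentation accuracy."""
    from .segmentation import as_clean, extract_edges as _edges

    rgb = np.stack([img.pixels] * 3, axis=-1).astype(np.uint8)
    edge = _edges(as_clean(clean_tissue)).edge
    rgb[edge] = (255, 0, 0)
    lo, hi = ts.frame_span
    for r in ts.h_rows:
        rgb[r, lo:hi] = (0, 160, 0)
    for c in ts.v_cols:
        rgb[lo:hi, c] = (0, 160, 0)
    return rgb


def run_batch(config: BatchConfig) -> BatchReport:
    """Process every PNG field in the input folder.

    Per field: load, match ROI file, threshold, exudate filtering, manual
    blanking, cleaning, edges, counting. Writes ``fields.csv`` (one row
    per field) and ``subjects.csv`` (pooled ratio-of-sums read-outs per
    subject), plus QC overlay PNGs when enabled. Deterministic given the
    config; per-field failures are logged, skipped and reported.
    """
    input_dir = Path(config.input_dir)
    output_dir = Path(config.output_dir)
    roi_dir = Path(config.roi_dir) if config.roi_dir else input_dir
    paths = sorted(input_dir.glob("*.png"))
    if not paths:
        raise UsageError(f"no PNG fields found in {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)

    ts = build_test_system(scale=config.scale_um_per_px)

    # one threshold per batch
    if config.threshold == "otsu-first":
        first = load_field(paths[0], scale=config.scale_um_per_px)
        threshold = suggest_threshold(first)
        logger.info("batch threshold from %s: %d", paths[0].name, threshold)
    else:
        threshold = int(config.threshold)

    rows = []
    failures: list[str] = []
    per_subject: dict[str, list[FieldCounts]] = {}
    for path in paths:
        try:
            img = load_field(path, scale=config.scale_um_per_px)
            rois = load_roiset(roi_dir / (path.stem + config.roi_suffix))
            raw = apply_threshold(img, threshold)
            filtered, removed = remove_auto_exudates(raw)
            if removed:
                logger.info(
                    "%s: auto-removed %d exudate particle(s), "
                    "areas %s px",
                    path.name,
                    len(removed),
                    [c.area for c in removed],
                )
            if not rois.is_empty():
                logger.info(
                    "%s: manual ROIs: %d non-parenchyma, %d exudates",
                    path.name,
                    len(rois.non_parenchyma),
                    len(rois.manual_exudates),
                )
            filtered = apply_manual_selections(filtered, rois)
            clean = clean_mask(filtered)
            from .counting import count_mask

            counts = count_mask(
                clean, rois, ts, source_id=path.name, threshold=threshold
            )
            if config.qc:
                Image.fromarray(
                    qc_overlay(img, clean.tissue, ts)
                ).save(output_dir / f"{path.stem}.qc.png")
        except Exception as exc:  # noqa: BLE001 - per-field isolation
            logger.error("field %s failed: %s", path.name, exc)
            failures.append(path.name)
            continue
        subject = _subject_of(path.stem, config.subject_pattern)
        per_subject.setdefault(subject, []).append(counts)
        rows.append(
            {
                "source_id": counts.source_id,
                "subject_id": subject,
                "p_nonpar": counts.p_nonpar,
                "p_ref": counts.p_ref,
                "p_sep": counts.p_sep,
                "i_h": counts.i_h,
                "i_v": counts.i_v,
                "i_total": counts.i_total,
                "threshold": threshold,
            }
        )

    fields_df = pd.DataFrame(rows, columns=FIELD_CSV_COLUMNS)
    subj_rows = []
    for subject in sorted(per_subject):
        s = stereology.summarize(
            per_subject[subject], subject_id=subject, d=config.d_um
        )
        subj_rows.append(
            {
                "subject_id": s.subject_id,
                "n_fields": s.n_fields,
                "sum_p_nonpar": s.sum_p_nonpar,
                "sum_p_ref": s.sum_p_ref,
                "sum_p_sep": s.sum_p_sep,
                "sum_i": s.sum_i,
                "vv_sep": s.vv_sep,
                "lm_um": s.lm,
                "lmw_um": s.lmw,
                "sv_air_per_um": s.sv_air,
            }
        )
    subjects_df = pd.DataFrame(subj_rows, columns=SUBJECT_CSV_COLUMNS)

    field_csv = output_dir / "fields.csv"
    subject_csv = output_dir / "subjects.csv"
    fields_df.to_csv(field_csv, index=False)
    subjects_df.to_csv(subject_csv, index=False)
    return BatchReport(
        fields=fields_df,
        subjects=subjects_df,
        threshold=threshold,
        field_csv=field_csv,
        subject_csv=subject_csv,
        failures=failures,
    )


@dataclass
class ValidationReport:
    """Computed-vs-theoretical agreement over a wallpaper series."""

    per_image: pd.DataFrame
    vv_sep: AgreementResult
    lm: AgreementResult
    seed: int


def run_validation_experiment(
    n_images: int = 11,
    fields_per_image: int = 20,
    seed: int = 0,
    scale: float = DEFAULT_SCALE_UM_PER_PX,
    vv_range: tuple[float, float] = (0.3, 0.9),
) -> ValidationReport:
    """The artificial-image validation experiment.

    Generates ``n_images`` binary wallpapers spanning septal densities
    ``vv_range``, randomly extracts ``fields_per_image`` 680x680 fields
    from each, counts them with the binary-input pipeline variant (the
    color-to-clean-mask steps are skipped), pools counts per image, and
    compares computed VVsep and Lm against the exact theoretical values
    by regression and Bland-Altman on relative differences (computed
    first, so underestimation is a negative bias). Fully seeded.
    """
    if n_images < 3:
        raise UsageError("need >= 3 images for regression")
    ts = build_test_system(scale=scale)
    series = wallpaper_series(n_images=n_images, vv_range=vv_range, seed=seed)
    rows = []
    for j, (spec, theory) in enumerate(series):
        img, _ = make_wallpaper(spec)
        fields = sample_fields(
            img,
            n=fields_per_image,
            seed=seed * 7919 + 31 * j + 1,
            scale=scale,
        )
        counts = [count_binary_field(f, ts) for f in fields]
        rows.append(
            {
                "image": j,
                "vv_sep_theory": theory.vv_sep,
                "lm_theory_um": theory.lm_um(scale),
                "vv_sep_computed": stereology.vv_sep(counts),
                "lm_computed_um": stereology.lm(counts),
                "sum_i": sum(c.i_total for c in counts),
            }
        )
    df = pd.DataFrame(rows)
    vv_res = method_agreement(
        df["vv_sep_computed"], df["vv_sep_theory"], percent=True
    )
    lm_res = method_agreement(
        df["lm_computed_um"], df["lm_theory_um"], percent=True
    )
    return ValidationReport(per_image=df, vv_sep=vv_res, lm=lm_res, seed=seed)
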