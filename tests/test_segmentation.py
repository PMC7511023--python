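"""Mask segmentation: exudate filtering, manual blanking, cleaning, edges."""

import numpy as np
import pytest

from alveomorph import (
    BinaryMask,
    RoiSet,
    StageError,
    apply_manual_selections,
    as_clean,
    clean_mask,
    extract_edges,
    make_histology_phantom,
    remove_auto_exudates,
)
from alveomorph.synthetic import PhantomParams


def raw(tissue):
    return BinaryMask(tissue=tissue, stage="raw")


def blank(size=680, value=False):
    return np.full((size, size), value, dtype=bool)


class TestRemoveAutoExudates:
    def test_small_interior_particle_removed(self):
        t = blank()
        t[300:305, 300:305] = True  # 25 px
        out, removed = remove_auto_exudates(raw(t))
        assert not out.tissue.any()
        assert len(removed) == 1
        assert removed[0].area == 25
        assert removed[0].centroid == (302.0, 302.0)

    def test_large_particle_kept_for_manual_selection(self):
        t = blank()
        t[300:340, 300:340] = True  # 1600 px > 1000
        out, removed = remove_auto_exudates(raw(t))
        np.testing.assert_array_equal(out.tissue, t)
        assert removed == []

    def test_border_particle_kept(self):
        t = blank()
        t[100:110, 0:10] = True  # touches column 0
        out, removed = remove_auto_exudates(raw(t))
        np.testing.assert_array_equal(out.tissue, t)
        assert removed == []

    def test_exact_1000px_removed_1001_kept(self):
        t = blank()
        t[100:125, 100:140] = True  # 25*40 = 1000
        out, _ = remove_auto_exudates(raw(t))
        assert not out.tissue.any()
        t2 = blank()
        t2[100:125, 100:140] = True
        t2[125, 100] = True  # 1001, 8-connected
        out2, _ = remove_auto_exudates(raw(t2))
        assert out2.tissue.sum() == 1001

    def test_never_adds_tissue(self):
        rng = np.random.default_rng(3)
        t = rng.random((680, 680)) < 0.3
        out, _ = remove_auto_exudates(raw(t))
        assert not (out.tissue & ~t).any()

    def test_stage_enforced(self):
        with pytest.raises(StageError):
            remove_auto_exudates(BinaryMask(blank(), stage="clean"))

    def test_phantom_truth_oracle(self):
        """Exactly the planted sub-1000 px interior particles go; the
        septal network and vessels stay (truth masks as oracle)."""
        ph = make_histology_phantom(PhantomParams(seed=7, noise_sd=0.0))
        tissue = ph.image.pixels <= 145  # midpoint of phase means
        out, removed = remove_auto_exudates(raw(tissue))
        assert len(removed) == ph.params.exudate_count
        assert not (out.tissue & ph.truth_exudates).any()
        np.testing.assert_array_equal(
            out.tissue, ph.truth_septa | ph.truth_vessels
        )


class TestManualSelections:
    def test_polygon_pixels_become_air(self):
        mask = BinaryMask(blank(value=True), stage="exudate_filtered")
        # closed 10x10 pixel block under the boundary-inclusive rule
        poly = [[200, 200], [209, 200], [209, 209], [200, 209]]
        rois = RoiSet(manual_exudates=[np.asarray(poly, dtype=float)])
        out = apply_manual_selections(mask, rois)
        assert (~out.tissue).sum() == 100
        assert not out.tissue[200:210, 200:210].any()

    def test_empty_roiset_is_identity(self):
        t = np.random.default_rng(4).random((680, 680)) < 0.5
        mask = BinaryMask(t, stage="exudate_filtered")
        out = apply_manual_selections(mask, RoiSet())
        np.testing.assert_array_equal(out.tissue, t)

    def test_overlapping_roles_blank_union(self):
        mask = BinaryMask(blank(value=True), stage="exudate_filtered")
        sq = lambda x0, y0, w: np.array(
            [[x0, y0], [x0 + w, y0], [x0 + w, y0 + w], [x0, y0 + w]], float
        )
        a = RoiSet(non_parenchyma=[sq(100, 100, 50)], manual_exudates=[sq(120, 120, 50)])
        b = RoiSet(non_parenchyma=[sq(120, 120, 50)], manual_exudates=[sq(100, 100, 50)])
        out_a = apply_manual_selections(mask, a)
        out_b = apply_manual_selections(mask, b)
        np.testing.assert_array_equal(out_a.tissue, out_b.tissue)


class TestCleanMask:
    def _ring_with_hole(self, hole_h, hole_w):
        t = blank()
        t[100:160, 100:160] = True
        t[120 : 120 + hole_h, 120 : 120 + hole_w] = False
        return BinaryMask(t, stage="exudate_filtered")

    def test_small_hole_filled(self):
        out = clean_mask(self._ring_with_hole(5, 10))  # 50 px hole
        assert out.tissue[120:125, 120:130].all()
        assert out.stage == "clean"

    def test_large_hole_preserved(self):
        out = clean_mask(self._ring_with_hole(20, 25))  # 500 px hole
        assert not out.tissue[125:135, 125:140].any()

    def test_isolated_pixel_removed_by_outlier_step(self):
        t = blank()
        t[340, 340] = True
        out = clean_mask(BinaryMask(t, stage="exudate_filtered"))
        assert not out.tissue.any()

    def test_filling_never_removes_tissue(self):
        rng = np.random.default_rng(5)
        t = rng.random((680, 680)) < 0.6
        out = clean_mask(
            BinaryMask(t, stage="exudate_filtered"),
            outlier_radius=0,
            closing_iterations=0,
        )
        assert not (t & ~out.tissue).any()

    def test_closing_idempotent(self):
        rng = np.random.default_rng(6)
        t = rng.random((680, 680)) < 0.5
        once = clean_mask(
            BinaryMask(t, "exudate_filtered"),
            hole_area_max=0,
            outlier_radius=0,
            closing_iterations=1,
        )
        twice = clean_mask(
            BinaryMask(t, "exudate_filtered"),
            hole_area_max=0,
            outlier_radius=0,
            closing_iterations=2,
        )
        np.testing.assert_array_equal(once.tissue, twice.tissue)

    def test_thick_septum_survives_median(self):
        t = blank()
        t[:, 300:303] = True  # 3 px wall spanning the image
        out = clean_mask(BinaryMask(t, "exudate_filtered"))
        assert out.tissue[:, 300:303].all()


class TestExtractEdges:
    def test_all_tissue_has_no_edges(self):
        assert not extract_edges(as_clean(blank(value=True))).edge.any()

    @pytest.mark.parametrize("a", [2, 5, 10, 63])
    def test_square_edge_count_closed_form(self, a):
        t = blank()
        t[200 : 200 + a, 300 : 300 + a] = True
        edge = extract_edges(as_clean(t)).edge
        assert edge.sum() == 4 * a - 4

    def test_single_pixel_is_its_own_edge(self):
        t = blank()
        t[10, 10] = True
        edge = extract_edges(as_clean(t)).edge
        assert edge.sum() == 1 and edge[10, 10]

    def test_edges_are_tissue_pixels_touching_air(self):
        rng = np.random.default_rng(8)
        t = rng.random((680, 680)) < 0.5
        edge = extract_edges(as_clean(t)).edge
        assert not (edge & ~t).any()
        # every edge pixel has a 4-neighbor of air inside the image
        padded = np.pad(t, 1, constant_values=True)
        has_air = (
            ~padded[:-2, 1:-1] | ~padded[2:, 1:-1]
            | ~padded[1:-1, :-2] | ~padded[1:-1, 2:]
        )
        np.testing.assert_array_equal(edge, t & has_air)


def test_pipeline_determinism():
    """Same raw mask and ROIs give bit-identical clean masks."""
    rng = np.random.default_rng(9)
    t = rng.random((680, 680)) < 0.55
    rois = RoiSet(
        non_parenchyma=[
            np.array([[50, 50], [200, 60], [180, 220], [40, 200]], float)
        ]
    )

    def run():
        filtered, _ = remove_auto_exudates(BinaryMask(t.copy(), "raw"))
        filtered = apply_manual_selections(filtered, rois)
        return clean_mask(filtered).tissue

    np.testing.assert_array_equal(run(), run())
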