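"""Test system geometry and the per-field counters."""

import numpy as np
import pytest

from alveomorph import (
    FieldImage,
    RoiSet,
    as_clean,
    build_test_system,
    count_binary_field,
    count_field,
    count_intersections,
    count_mask,
    count_pref,
    count_psep,
    extract_edges,
)


def square_poly(x0, y0, x1, y1):
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


FULL_FRAME = square_poly(0, 0, 680, 680)
LEFT_HALF = square_poly(0, 0, 340, 680)  # splits the 8 columns 4/4


class TestTestSystem:
    def test_geometry(self, ts):
        assert ts.n_points == 64
        assert ts.total_line_length_px == 16 * 567
        assert ts.frame_origin == 56
        assert ts.d_px == pytest.approx(141.75)
        # d in um consistent with d in px at the working scale
        assert abs(ts.d_px * ts.scale_um_per_px - ts.d_um) < 0.5

    def test_grid_points_are_line_crossings(self, ts):
        pts = {tuple(p) for p in ts.grid_points}
        expected = {(c, r) for r in ts.h_rows for c in ts.v_cols}
        assert pts == expected

    def test_lines_inside_frame(self, ts):
        lo, hi = ts.frame_span
        assert all(lo <= r < hi for r in ts.h_rows)
        assert all(lo <= c < hi for c in ts.v_cols)

    def test_densified_system_scales(self):
        ts4 = build_test_system(density=4)
        assert ts4.n_points == 32 * 32
        assert ts4.d_px == pytest.approx(141.75 / 4)
        assert ts4.d_um == pytest.approx(104 / 4)


class TestCountPref:
    def test_empty_roiset(self, ts, empty_rois):
        assert count_pref(empty_rois, ts) == (0, 64)

    def test_full_cover(self, ts):
        rois = RoiSet(non_parenchyma=[FULL_FRAME])
        assert count_pref(rois, ts) == (64, 0)

    def test_left_half_cover(self, ts):
        rois = RoiSet(non_parenchyma=[LEFT_HALF])
        assert count_pref(rois, ts) == (32, 32)
        # exhaustive oracle: count grid points with x <= 340
        assert sum(1 for x, y in ts.grid_points if x <= 340) == 32

    def test_growing_polygon_never_increases_pref(self, ts):
        prev_ref = 64
        for half in (100, 250, 400, 680):
            rois = RoiSet(non_parenchyma=[square_poly(0, 0, half, 680)])
            _, p_ref = count_pref(rois, ts)
            assert p_ref <= prev_ref
            prev_ref = p_ref


class TestCountPsep:
    def test_all_tissue(self, ts, empty_rois):
        t = np.ones((680, 680), dtype=bool)
        assert count_psep(as_clean(t), empty_rois, ts) == 64

    def test_all_air(self, ts, empty_rois):
        t = np.zeros((680, 680), dtype=bool)
        assert count_psep(as_clean(t), empty_rois, ts) == 0

    def test_left_half_tissue(self, ts, empty_rois):
        t = np.zeros((680, 680), dtype=bool)
        t[:, :340] = True
        assert count_psep(as_clean(t), empty_rois, ts) == 32

    def test_nonpar_points_excluded(self, ts):
        t = np.ones((680, 680), dtype=bool)
        rois = RoiSet(non_parenchyma=[LEFT_HALF])
        assert count_psep(as_clean(t), rois, ts) == 32


class TestCountIntersections:
    def test_empty_edge(self, ts, empty_rois):
        from alveomorph.segmentation import EdgeMask

        edge = EdgeMask(np.zeros((680, 680), dtype=bool))
        assert count_intersections(edge, empty_rois, ts) == (0, 0, 0)

    def test_vertical_stripe(self, ts, empty_rois):
        """A full-height tissue stripe: each horizontal line crosses two
        interfaces; vertical lines lie wholly inside or outside."""
        t = np.zeros((680, 680), dtype=bool)
        t[:, 290:390] = True
        edge = extract_edges(as_clean(t))
        assert count_intersections(edge, empty_rois, ts) == (16, 0, 16)

    def test_interior_square_12_crossings(self, ts, empty_rois):
        """A tissue square crossed by exactly 3 h- and 3 v-lines gives
        two crossings per crossing line: 12 intersections."""
        t = np.zeros((680, 680), dtype=bool)
        t[150:321, 150:321] = True  # spans lines at 162, 233, 304
        edge = extract_edges(as_clean(t))
        i_h, i_v, i_total = count_intersections(edge, empty_rois, ts)
        assert (i_h, i_v, i_total) == (6, 6, 12)

    def test_run_counts_once(self, ts, empty_rois):
        """A line lying along a tissue edge is one contiguous run, hence
        one intersection."""
        t = np.zeros((680, 680), dtype=bool)
        r = ts.h_rows[0]
        t[r : r + 30, 200:500] = True  # top edge row == first test line
        edge = extract_edges(as_clean(t))
        i_h, _, _ = count_intersections(edge, empty_rois, ts)
        assert i_h >= 1  # the long run along row r counts exactly once...
        # ...plus the two side-wall crossings of any other crossing line
        assert i_h == 1 + 2 * sum(1 for rr in ts.h_rows if r < rr < r + 30)

    def test_nonpar_runs_excluded(self, ts):
        t = np.zeros((680, 680), dtype=bool)
        t[:, 290:390] = True
        edge = extract_edges(as_clean(t))
        rois = RoiSet(non_parenchyma=[square_poly(250, 0, 430, 680)])
        assert count_intersections(edge, rois, ts) == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_rectangles_match_sign_change_oracle(self, ts, empty_rois, seed):
        """For air rectangles strictly inside the frame, intersections
        equal the number of tissue/air transitions along each test line
        (independent brute-force oracle). Rectangle edges are kept >= 2 px
        away from all line positions to avoid grazing contact."""
        rng = np.random.default_rng(seed)
        t = np.ones((680, 680), dtype=bool)
        forbidden = set()
        for p in np.concatenate([ts.h_rows, ts.v_cols]):
            forbidden.update(range(p - 2, p + 3))
        quadrants = [(70, 330), (350, 610)]
        for qr in quadrants:
            for qc in quadrants:
                for _ in range(50):
                    r0 = int(rng.integers(qr[0], qr[1] - 80))
                    c0 = int(rng.integers(qc[0], qc[1] - 80))
                    h = int(rng.integers(20, 70))
                    w = int(rng.integers(20, 70))
                    corners = {r0, r0 + h - 1, c0, c0 + w - 1}
                    edges_rc = {r0 - 1, r0 + h, c0 - 1, c0 + w}
                    if (corners | edges_rc) & forbidden:
                        continue
                    t[r0 : r0 + h, c0 : c0 + w] = False
                    break
        edge = extract_edges(as_clean(t))
        _, _, i_total = count_intersections(edge, empty_rois, ts)
        lo, hi = ts.frame_span
        oracle = 0
        for r in ts.h_rows:
            vals = t[r, lo:hi]
            oracle += int(np.sum(vals[1:] != vals[:-1]))
        for c in ts.v_cols:
            vals = t[lo:hi, c]
            oracle += int(np.sum(vals[1:] != vals[:-1]))
        assert i_total == oracle > 0


class TestCountField:
    def test_uniform_dark_field(self, ts, empty_rois, uniform_field):
        c = count_field(uniform_field(30), empty_rois, t=128, ts=ts)
        assert (c.p_ref, c.p_sep, c.i_total) == (64, 64, 0)

    def test_uniform_bright_field(self, ts, empty_rois, uniform_field):
        c = count_field(uniform_field(220), empty_rois, t=128, ts=ts)
        assert (c.p_ref, c.p_sep, c.i_total) == (64, 0, 0)

    def test_binary_field_matches_standalone_counters(self, ts, empty_rois):
        from alveomorph import make_wallpaper, sample_fields
        from alveomorph.synthetic import FigureSpec, WallpaperSpec

        spec = WallpaperSpec(
            tile=340,
            figures_per_tile=[FigureSpec("square", 120), FigureSpec("rectangle", 90, 140)],
            seed=11,
        )
        img, _ = make_wallpaper(spec)
        field = sample_fields(img, n=1, seed=5)[0]
        c = count_binary_field(field, ts)
        tissue = field.pixels < 128
        manual = count_mask(as_clean(tissue), empty_rois, ts)
        assert (c.p_ref, c.p_sep, c.i_h, c.i_v) == (
            manual.p_ref,
            manual.p_sep,
            manual.i_h,
            manual.i_v,
        )

    def test_invariant_pnonpar_plus_pref(self, ts):
        for half in (0, 120, 340, 680):
            polys = (
                [square_poly(0, 0, half, 680)] if half else []
            )
            p_nonpar, p_ref = count_pref(RoiSet(non_parenchyma=polys), ts)
            assert p_nonpar + p_ref == 64
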