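"""Morphometry: ellipse/rectangle fitting and Steger centerline recovery."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from skimage.draw import disk

from spermorph.geometry import HEAD, MIDPIECE, TAIL
from spermorph.morphometry import (
    DegenerateMaskError,
    PartMaskSet,
    fit_head,
    fit_midpiece,
    measure_instance,
    min_area_rect,
)
from spermorph.steger import EmptyCenterlineError, steger_centerline
from spermorph.synth import _bar_mask, _ellipse_mask, _tube_mask


def brute_force_min_rect(mask):
    """Oracle: min-area rectangle over hull-edge-aligned orientations."""
    from spermorph.morphometry import _contour_points
    pts = _contour_points(mask)
    hull = pts[ConvexHull(pts).vertices]
    best = None
    n = len(hull)
    for i in range(n):
        e = hull[(i + 1) % n] - hull[i]
        norm = np.linalg.norm(e)
        if norm == 0:
            continue
        u = e / norm
        v = np.array([-u[1], u[0]])
        a = hull @ u
        b = hull @ v
        area = (a.max() - a.min()) * (b.max() - b.min())
        if best is None or area < best[0]:
            best = (area, a.max() - a.min(), b.max() - b.min())
    _, l0, l1 = best
    return max(l0, l1), min(l0, l1)


class TestHeadFitting:
    def test_disc_has_unit_ellipticity(self):
        mask = np.zeros((60, 60), bool)
        rr, cc = disk((30.3, 30.3), 15)
        mask[rr, cc] = True
        _, _, f = fit_head(mask, 0.1)
        assert f["head_ellipticity"] == pytest.approx(1.0, abs=0.02)
        assert f["head_length_um"] == pytest.approx(f["head_width_um"], abs=0.05)
        assert f["head_length_um"] == pytest.approx(3.0, abs=0.05)

    def test_rendered_ellipse_axes_recovered(self):
        mask = _ellipse_mask((100, 100), (50.3, 50.3), 20, 10, 0.0)
        _, _, f = fit_head(mask, 0.1)
        assert f["head_length_um"] == pytest.approx(4.0, abs=0.05)
        assert f["head_width_um"] == pytest.approx(2.0, abs=0.05)
        assert f["head_ellipticity"] == pytest.approx(2.0, abs=0.05)

    def test_normal_length_band_flag(self):
        small = _ellipse_mask((120, 120), (60.0, 60.0), 20, 12, 0.2)  # 4.0 um at 0.1
        _, _, f = fit_head(small, 0.1)
        assert f["normal_length"]
        _, _, f2 = fit_head(small, 0.13)  # 5.2 um: outside 3.7-4.7
        assert not f2["normal_length"]

    def test_eccentricity_mode(self):
        mask = _ellipse_mask((100, 100), (50.3, 50.3), 20, 10, 0.0)
        _, _, f = fit_head(mask, 0.1, ellipticity_mode="eccentricity")
        assert f["head_ellipticity"] == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_degenerate_mask_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        with pytest.raises(DegenerateMaskError):
            fit_head(mask, 0.1)


class TestMidpieceFitting:
    def test_axis_aligned_bar_exact(self):
        mask = np.zeros((60, 80), bool)
        mask[27:33, 20:60] = True
        _, f = fit_midpiece(mask, 0.1)
        assert f["mid_length_um"] == pytest.approx(4.0, abs=1e-6)
        assert f["mid_width_um"] == pytest.approx(0.6, abs=1e-6)
        assert f["mid_angle_deg"] == pytest.approx(0.0, abs=1e-6)

    def test_rotated_bar_angle_within_one_degree(self):
        a = np.radians(30)
        mask = _bar_mask((100, 100), np.array([40.2, 15.2]),
                         np.array([40.2 + 40 * np.sin(a), 15.2 + 40 * np.cos(a)]), 6.0)
        _, f = fit_midpiece(mask, 0.1)
        assert f["mid_angle_deg"] == pytest.approx(30.0, abs=1.0)
        assert f["mid_length_um"] == pytest.approx(4.0, abs=0.1)

    def test_square_angle_deterministic_in_first_quadrant(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        rect, f = fit_midpiece(mask, 0.1)
        assert 0.0 <= f["mid_angle_deg"] < 90.0
        rect2, f2 = fit_midpiece(mask, 0.1)
        assert f["mid_angle_deg"] == f2["mid_angle_deg"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_min_area_rect_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((30, 30), bool)
        rr, cc = disk((rng.uniform(12, 18), rng.uniform(12, 18)), rng.uniform(4, 8))
        mask[np.clip(rr, 0, 29), np.clip(cc, 0, 29)] = True
        mask[rng.integers(5, 25, 10), rng.integers(5, 25, 10)] = True
        rect = min_area_rect(mask)
        bl, bw = brute_force_min_rect(mask)
        assert rect.length_px == pytest.approx(bl, rel=1e-6)
        assert rect.width_px == pytest.approx(bw, rel=1e-6)


class TestStegerCenterline:
    def test_straight_line_length_width_angle(self):
        pts = np.array([[50.3, 20.3], [50.3, 220.3]])
        mask = _tube_mask((100, 260), pts, 4.0)
        cl = steger_centerline(mask, width_range_px=(3, 5))
        assert cl.arc_length == pytest.approx(200.0, abs=4.0)
        assert cl.mean_width == pytest.approx(4.0, abs=1.0)
        assert cl.end_chord_angle_deg() == pytest.approx(0.0, abs=1.0)

    @pytest.mark.parametrize("radius", [30, 60])
    def test_semicircle_arc_length(self, radius):
        th = np.linspace(0, np.pi, 300)
        cr, cc = 20.0, radius + 20.0
        pts = np.stack([cr + radius * np.sin(th), cc + radius * np.cos(th)], 1)
        shape = (radius + 40, 2 * radius + 40)
        mask = _tube_mask(shape, pts, 4.0)
        cl = steger_centerline(mask, width_range_px=(3, 5))
        assert cl.arc_length == pytest.approx(np.pi * radius, rel=0.03)

    def test_empty_input_raises(self):
        with pytest.raises(EmptyCenterlineError):
            steger_centerline(np.zeros((30, 30), dtype=bool))

    def test_subpixel_points_on_ridge(self):
        pts = np.array([[40.5, 10.0], [40.5, 90.0]])
        mask = _tube_mask((80, 100), pts, 4.0)
        cl = steger_centerline(mask, width_range_px=(3, 5))
        assert np.allclose(cl.points[:, 0], 40.5, atol=0.5)


class TestMeasureInstance:
    def _instance(self, scene):
        g = scene.geometries[0]
        sel = scene.instance_map == g.instance_id
        return g, PartMaskSet(
            g.instance_id,
            head=sel & (scene.part_map == HEAD),
            midpiece=sel & (scene.part_map == MIDPIECE),
            tail=sel & (scene.part_map == TAIL),
            pixel_size_um=0.2)

    def test_nine_parameters_recovered(self, single_sperm_scene):
        g, parts = self._instance(single_sperm_scene)
        m = measure_instance(parts)
        t = g.params
        assert m.head_length_um == pytest.approx(t.head_length_um, abs=0.25)
        assert m.head_width_um == pytest.approx(t.head_width_um, abs=0.25)
        assert m.head_ellipticity == pytest.approx(t.head_ellipticity, rel=0.1)
        assert m.mid_length_um == pytest.approx(t.mid_length_um, abs=0.3)
        assert m.mid_width_um == pytest.approx(t.mid_width_um, abs=0.3)
        assert m.tail_length_um == pytest.approx(t.tail_length_um, rel=0.03)
        assert m.tail_width_um == pytest.approx(t.tail_width_um, abs=0.25)

    def test_missing_tail_flags_absent(self, single_sperm_scene):
        g, parts = self._instance(single_sperm_scene)
        parts.tail = None
        m = measure_instance(parts)
        assert m.tail_length_um is None
        assert m.head_length_um is not None
        assert "tail" in m.missing_parts

    def test_all_empty_instance_raises(self):
        empty = np.zeros((20, 20), bool)
        parts = PartMaskSet(1, head=empty, midpiece=empty, tail=empty)
        with pytest.raises(DegenerateMaskError):
            measure_instance(parts)

    def test_record_column_order(self):
        from spermorph.geometry import MORPH_COLUMNS
        assert MORPH_COLUMNS == (
            "head_length_um", "head_width_um", "head_ellipticity",
            "mid_length_um", "mid_width_um", "mid_angle_deg",
            "tail_length_um", "tail_width_um", "tail_angle_deg")


class TestInvariances:
    def test_rotation_by_90_degrees(self, single_sperm_scene):
        g, = single_sperm_scene.geometries
        sel = single_sperm_scene.instance_map == g.instance_id
        head = sel & (single_sperm_scene.part_map == HEAD)
        _, rect, f = fit_head(head, 0.2)
        _, rect90, f90 = fit_head(np.rot90(head), 0.2)
        assert f90["head_length_um"] == pytest.approx(f["head_length_um"], abs=0.2 * 1.0)
        assert f90["head_width_um"] == pytest.approx(f["head_width_um"], abs=0.2 * 1.0)
        d = abs(np.degrees(rect.angle_rad) - np.degrees(rect90.angle_rad)) % 180
        assert min(d, 180 - d) == pytest.approx(90.0, abs=2.0)

    def test_scale_linearity_in_pixel_size(self, single_sperm_scene):
        g, = single_sperm_scene.geometries
        sel = single_sperm_scene.instance_map == g.instance_id
        head = sel & (single_sperm_scene.part_map == HEAD)
        _, _, f1 = fit_head(head, 0.2)
        _, _, f2 = fit_head(head, 0.4)
        assert f2["head_length_um"] == pytest.approx(2 * f1["head_length_um"])
        assert f2["head_width_um"] == pytest.approx(2 * f1["head_width_um"])
        assert f2["head_ellipticity"] == pytest.approx(f1["head_ellipticity"])
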