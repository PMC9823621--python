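"""Cross-section construction, transforms and rasterization."""

import math

import numpy as np
import pytest

from frustulight.geometry import (GeometryScene, SceneError, add_girdle_bands,
                                  assemble_frustule, build_analytic_component,
                                  build_longitudinal_cs, build_vertical_cs,
                                  rasterize, transform_scene, vectorize)
from frustulight.params import CrossSectionSpec, OpticalConstants, ValveParameters


def cs(family, index, **kw):
    return CrossSectionSpec(family=family, index=index, **kw)


class TestLongitudinalCS:
    def test_plain_slab_cs_has_one_silica_polygon(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "5"))
        assert len(scene.silica) == 1
        # slab thickness D_v between the mantle edges
        x0, y0, x1, y1 = scene.bounds
        assert y1 - y0 == pytest.approx(valve_params.L_v, rel=0.02)

    def test_slab_thickness_is_D_v_away_from_mantle(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "5"))
        from shapely.geometry import LineString
        line = LineString([(0.0, 0.0), (20.0, 0.0)])
        seg = scene.union.intersection(line)
        assert seg.length == pytest.approx(valve_params.D_v, abs=0.005)

    def test_degenerate_spec_reduces_to_exact_rectangle(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "5", W_M_CS=0.0),
                                      fillet_radius=0.0)
        x0, y0, x1, y1 = scene.bounds
        assert (x1 - x0) == pytest.approx(valve_params.D_v, abs=1e-9)
        assert (y1 - y0) == pytest.approx(valve_params.L_v, abs=1e-9)
        assert scene.area == pytest.approx(valve_params.D_v * valve_params.L_v,
                                           rel=1e-9)

    def test_grid_cs_unit_count_and_pitch(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "4"))
        g = scene.meta["grid"]
        assert g["n_units"] == 11
        assert g["d"] == pytest.approx(0.500)
        centers = np.array(g["unit_centers"])
        np.testing.assert_allclose(np.diff(centers), 0.5, atol=1e-12)

    def test_defect_variant_preserves_silica_area(self, valve_params):
        a = build_longitudinal_cs(valve_params, cs("long", "4"))
        b = build_longitudinal_cs(valve_params, cs("long", "4*"))
        assert b.area == pytest.approx(a.area, rel=5e-3)
        # but the geometry differs at the defect site
        assert a.union.symmetric_difference(b.union).area > 0.01

    def test_nodule_cs_interrupts_grid(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "3"))
        centers = np.array(scene.meta["grid"]["unit_centers"])
        # no unit centre inside the nodule zone
        y_nod = valve_params.nodule_offset
        assert np.all(np.abs(centers - y_nod) > valve_params.W_nod / 2)
        # nodule thickening present: max extent reaches D_nod
        x0, _, x1, _ = scene.bounds
        face = scene.meta["face_x"]
        assert x1 - face >= valve_params.D_nod - 0.01

    def test_sternum_cs_thicker_than_plain_slab(self, valve_params):
        s2 = build_longitudinal_cs(valve_params, cs("long", "2"))
        s5 = build_longitudinal_cs(valve_params, cs("long", "5"))
        assert s2.area > s5.area

    def test_raphe_cs_has_two_slits(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "1"),
                                      fillet_radius=0.0)
        from shapely.geometry import LineString
        probe_y = np.linspace(-1.0, 1.0, 2001)
        face = scene.meta["face_x"]
        line_x = face + valve_params.D_v / 2
        hits = [scene.union.intersects(
            LineString([(line_x - 1e-4, y), (line_x + 1e-4, y)]))
            for y in probe_y]
        runs = np.diff(np.array(hits).astype(int))
        assert (runs == -1).sum() >= 2      # at least two open slits

    def test_unknown_index_rejected(self, valve_params):
        with pytest.raises(ValueError):
            cs("long", "9")


class TestVerticalCS:
    def test_raphe_slit_is_the_only_difference(self, valve_params):
        with_slit = build_vertical_cs(valve_params, cs("ver", "4"))
        without = build_vertical_cs(valve_params, cs("ver", "5"))
        diff = without.area - with_slit.area
        slit_area = valve_params.W_ra * valve_params.D_S
        assert diff == pytest.approx(slit_area, rel=0.35)
        assert len(with_slit.silica) == 2        # slit splits the CS in two
        assert len(without.silica) == 1

    def test_areolae_grid_pitch(self, valve_params):
        scene = build_vertical_cs(valve_params, cs("ver", "1"))
        g = scene.meta["grid"]
        assert g["d"] == pytest.approx(0.214)
        centers = np.sort(np.array(g["unit_centers"]))
        gaps = np.diff(centers)
        # uniform pitch on each side of the nodule
        assert np.isclose(gaps, 0.214, atol=1e-9).sum() >= len(gaps) - 1

    def test_triangular_nodule_degenerates_with_thickness(self):
        p = ValveParameters(D_nod=0.171, D_S=0.1705)
        tri = build_vertical_cs(p, cs("ver", "2"))
        slab = build_vertical_cs(p, cs("ver", "5"))
        # a vanishing triangle leaves nearly the flat slab profile
        assert tri.area == pytest.approx(slab.area, rel=1e-3)


class TestAnalyticComponents:
    def test_grid_span_is_pitch_arithmetic(self):
        scene = build_analytic_component(
            "grid", {"d": 0.5, "ff": 0.7, "D": 0.17, "N": 11})
        _, y0, _, y1 = scene.bounds
        assert (y1 - y0) == pytest.approx(10 * 0.5 + 0.7 * 0.5, abs=1e-9)
        assert len(scene.silica) == 11

    def test_slab_dimensions(self):
        scene = build_analytic_component("slab", {"L": 20.0, "D": 0.17})
        x0, y0, x1, y1 = scene.bounds
        assert (x1 - x0, y1 - y0) == pytest.approx((0.17, 20.0))

    def test_mantle_strip_dimensions_and_tilt(self):
        straight = build_analytic_component("mantle", {"W": 0.184, "h": 2.0})
        x0, y0, x1, y1 = straight.bounds
        assert (x1 - x0, y1 - y0) == pytest.approx((2.0, 0.184))
        tilted = build_analytic_component("mantle",
                                          {"W": 0.184, "h": 2.0, "tilt": 20.0})
        assert tilted.area == pytest.approx(straight.area, rel=1e-9)
        assert tilted.bounds[3] - tilted.bounds[1] > 0.184 + 0.1

    def test_bad_fill_factor_rejected(self):
        with pytest.raises(SceneError):
            build_analytic_component("grid", {"d": 0.5, "ff": 1.5,
                                              "D": 0.17, "N": 5})


class TestGirdleAndFrustule:
    def test_girdle_bands_add_four_polygons(self, valve_params, cs_long5):
        before = len(cs_long5.silica)
        scene = add_girdle_bands(cs_long5, valve_params)
        assert len(scene.silica) == before + 4

    def test_band_aspect_ratio(self, valve_params):
        assert (valve_params.H_girdle / valve_params.W_girdle
                == pytest.approx(15.4, abs=0.1))

    def test_zero_spacing_bands_are_contiguous(self, valve_params, cs_long5):
        import dataclasses
        p0 = dataclasses.replace(valve_params, d_girdle=1e-12)
        scene = add_girdle_bands(cs_long5, p0)
        assert len(scene.silica) >= len(cs_long5.silica)  # allowed, not an error

    def test_frustule_counts_valves_and_bands(self, valve_params, cs_long5):
        scene = assemble_frustule(cs_long5, valve_params)
        # 1 epivalve + 4 bands + 1 hypovalve (each valve one polygon here)
        assert len(scene.silica) == 6
        assert scene.meta["frustule"]

    def test_hypovalve_is_scaled_mirror(self, valve_params, cs_long5):
        scene = assemble_frustule(cs_long5, valve_params, scale_hypovalve=0.97)
        areas = sorted(p.area for p in scene.silica)
        epi = cs_long5.area
        assert areas[-1] == pytest.approx(epi, rel=1e-6)
        assert areas[-2] == pytest.approx(epi * 0.97**2, rel=1e-6)

    def test_upscaled_hypovalve_rejected(self, valve_params, cs_long5):
        with pytest.raises(SceneError):
            assemble_frustule(cs_long5, valve_params, scale_hypovalve=1.0)

    def test_nodule_frustule_has_two_nodule_lenses(self, valve_params):
        cs3 = build_longitudinal_cs(valve_params, cs("long", "3"))
        scene = assemble_frustule(cs3, valve_params)
        # thickness D_nod reached on both the epivalve and hypovalve side
        xs = [p.bounds for p in scene.silica]
        thick = [b for b in xs if (b[2] - b[0]) > valve_params.D_nod - 0.02
                 and (b[2] - b[0]) < 1.0]
        assert len(thick) >= 2


class TestTransforms:
    def test_double_rotation_is_identity(self, cs_long5):
        twice = transform_scene(transform_scene(cs_long5, rotate_180=True),
                                rotate_180=True)
        assert twice.union.symmetric_difference(cs_long5.union).area < 1e-9

    def test_tilt_and_untilt_is_identity(self, cs_long5):
        back = transform_scene(transform_scene(cs_long5, tilt_deg=10.0),
                               tilt_deg=-10.0)
        assert back.union.symmetric_difference(cs_long5.union).area < 1e-6

    def test_area_invariant_under_transform(self, cs_long5):
        for kwargs in ({"rotate_180": True}, {"tilt_deg": 17.0},
                       {"rotate_180": True, "tilt_deg": -8.0}):
            t = transform_scene(cs_long5, **kwargs)
            assert t.area == pytest.approx(cs_long5.area, rel=1e-6)

    def test_rotation_turns_mantle_towards_source(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "5"))
        flipped = transform_scene(scene, rotate_180=True)
        # mantle tips (largest x before) now sit at smallest x
        assert flipped.bounds[0] == pytest.approx(
            2 * scene.union.centroid.x - scene.bounds[2], abs=1e-6)


class TestRasterize:
    def test_empty_scene_is_uniform_medium(self):
        scene = GeometryScene([], OpticalConstants(n_m=1.33), "empty", {})
        g = rasterize(scene, 0.05, box=(0, 0, 1, 1))
        assert np.all(g.n == 1.33)

    def test_slab_raster_area_within_one_percent(self):
        scene = build_analytic_component("slab", {"L": 20.0, "D": 0.17})
        g = rasterize(scene, 0.01, box=(3, -11, 6, 11))
        assert g.silica_area() == pytest.approx(scene.area, rel=0.01)

    @pytest.mark.parametrize("index", ["1", "3", "4", "5"])
    def test_cs_raster_vectorize_round_trip(self, valve_params, index):
        scene = build_longitudinal_cs(valve_params, cs("long", index))
        g = rasterize(scene, 0.01)
        assert g.silica_area() == pytest.approx(scene.area, rel=0.01)
        polys = vectorize(g)
        total = sum(p.area for p in polys)
        assert total == pytest.approx(scene.area, rel=0.01)

    def test_grid_cs_raster_shows_the_striae_gaps(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "4"))
        g = rasterize(scene, 0.01, box=(0, -6, 8, 6))
        face = scene.meta["face_x"]
        ix = int((face + valve_params.D_v / 2) / 0.01)
        gy0, _, gy1 = scene.meta["grid_bbox"][1], None, scene.meta["grid_bbox"][3]
        yc = g.y_centers()
        row = (g.n[ix, :] > 1.2)[(yc > gy0) & (yc < gy1)]
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], (~row).astype(int), [0]))))
        n_gaps = len(edges) // 2
        assert n_gaps == scene.meta["grid"]["n_units"] - 1

    def test_antialiased_values_stay_between_indices(self, valve_params):
        scene = build_longitudinal_cs(valve_params, cs("long", "5"))
        g = rasterize(scene, 0.02)
        assert g.n.min() >= 1.0 - 1e-12
        assert g.n.max() <= 1.46 + 1e-12

    def test_too_coarse_resolution_refused(self, cs_long5):
        with pytest.raises(SceneError, match="too coarse"):
            rasterize(cs_long5, 0.05, lam_min_nm=300.0)

    def test_lens_grid_and_rect_grid_differ_only_at_the_sag(self, valve_params):
        lens_cs = build_longitudinal_cs(valve_params, cs("long", "4"),
                                        fillet_radius=0.0)
        g = lens_cs.meta["grid"]
        rect = build_analytic_component(
            "grid", {"d": g["d"], "ff": g["ff"], "D": valve_params.D_v,
                     "N": g["n_units"]})
        # identical pitch and unit count
        assert rect.meta["grid"]["d"] == g["d"]
        assert rect.meta["grid"]["n_units"] == g["n_units"]
        res = 0.01
        gy0, gy1 = lens_cs.meta["grid_bbox"][1], lens_cs.meta["grid_bbox"][3]
        box = (3.8, gy0 + 0.1, 4.4, gy1 - 0.1)
        ra = rasterize(lens_cs, res, box=box)
        rb = rasterize(rect, res, box=box)
        differs = np.abs(ra.n - rb.n) > 1e-6
        xs = ra.x_centers()[np.nonzero(differs)[0]]
        face = valve_params.D_v  # sag occupies the internal 0.07 µm
        sag_start = 4.0 + valve_params.D_v - 0.07
        assert xs.min() >= sag_start - 2 * res


class TestFillet:
    def test_fillet_changes_area_by_less_than_two_percent(self, valve_params):
        for index in ("4", "5", "2"):
            sharp = build_longitudinal_cs(valve_params, cs("long", index),
                                          fillet_radius=0.0)
            smooth = build_longitudinal_cs(valve_params, cs("long", index))
            assert smooth.area == pytest.approx(sharp.area, rel=0.02)
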