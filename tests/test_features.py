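"""Observable extraction: R/T, focusing spots, photonic jets, Talbot planes."""

import numpy as np
import pytest

from frustulight.features import (FeatureError, characterize_pj,
                                  detect_focus_spots, extract_RT,
                                  extract_talbot, find_gmr, track_spot)
from frustulight.fixtures import FixtureSpec, make_fixture
from frustulight.geometry import GeometryScene, build_analytic_component
from frustulight.params import OpticalConstants
from frustulight.solver import SimulationConfig

from conftest import solve_scene


class TestExtractRT:
    def test_homogeneous_scene_reflects_nothing(self, small_config, small_box):
        scene = GeometryScene([], OpticalConstants(), "h",
                              {"face_x": 4.0, "exit_x": 4.0})
        fm = solve_scene(scene, 500.0, small_config, small_box)
        R, T = extract_RT(fm, scene)
        assert R == pytest.approx(0.0, abs=1e-3)
        assert T == pytest.approx(1.0, abs=0.02)

    def test_window_that_does_not_fit_is_reported(self, small_config,
                                                  small_box, slab_scene_air):
        fm = solve_scene(slab_scene_air, 600.0, small_config, small_box)
        with pytest.raises(FeatureError, match="window"):
            extract_RT(fm, slab_scene_air, margin=3.5)


class TestFocusSpots:
    def test_homogeneous_field_has_no_spots(self, homogeneous_field):
        assert detect_focus_spots(homogeneous_field, 4.0) == []

    def test_spots_sorted_by_strength(self, small_config, small_box):
        scene = build_analytic_component("slab", {"L": 4.0, "D": 0.17},
                                         OpticalConstants(), face_x=4.0)
        fm = solve_scene(scene, 400.0, small_config, small_box)
        spots = detect_focus_spots(fm, scene.meta["exit_x"])
        assert len(spots) > 0
        strengths = [s.E_Norm_f for s in spots]
        assert strengths == sorted(strengths, reverse=True)
        assert all(s.Z_f >= 0 and s.E_Norm_f > 1.0 for s in spots)

    def test_two_slit_scene_splits_the_pattern(self, small_config, small_box):
        fx = make_fixture(FixtureSpec("two_slit", {"separation": 2.4,
                                                   "slit_width": 0.5}))
        fm = solve_scene(fx.scene, 450.0, small_config, small_box)
        spots = detect_focus_spots(fm, fx.scene.meta["exit_x"])
        ys = np.array([s.centroid[1] for s in spots if s.E_Norm_f > 1.15])
        # bright spots cluster behind each slit, i.e. on both sides
        assert (ys > 0.4).any() and (ys < -0.4).any()

    def test_tracking_follows_nearest_centroid(self):
        from frustulight.features import FocusSpot
        mk = lambda y, E: FocusSpot(1.0, 0.5, E, (6.0, y), (6.0, y))
        lists = [[mk(0.0, 1.5), mk(2.0, 1.4)],
                 [mk(1.9, 1.2), mk(-0.1, 1.3)]]
        tracked = track_spot(lists, start=lists[0][1])
        assert tracked[1].centroid[1] == pytest.approx(1.9)


class TestPhotonicJet:
    def test_nodule_lens_produces_a_jet_on_axis(self, small_config, small_box):
        lens = build_analytic_component("lens", {"width": 0.86, "D": 0.38,
                                                 "sag": 0.21},
                                        OpticalConstants(), face_x=4.0)
        fm = solve_scene(lens, 450.0, small_config, small_box)
        pj = characterize_pj(fm, lens.union.bounds)
        assert pj.E_Norm_PJ > 1.3
        assert abs(pj.angle_deg) < 12.0
        assert pj.waist > 0

    def test_no_jet_without_contrast(self, small_config, small_box):
        lens = build_analytic_component("lens", {"width": 0.86, "D": 0.38,
                                                 "sag": 0.21},
                                        OpticalConstants(1.46, 1.46),
                                        face_x=4.0)
        fm = solve_scene(lens, 450.0, small_config, small_box)
        with pytest.raises(FeatureError, match="threshold"):
            characterize_pj(fm, lens.union.bounds)

    def test_jet_axis_follows_tilted_incidence(self, small_box):
        lens = build_analytic_component("lens", {"width": 0.86, "D": 0.38,
                                                 "sag": 0.21},
                                        OpticalConstants(), face_x=4.0)
        angles = []
        for theta in (0.0, 15.0):
            cfg = SimulationConfig(box_width_x=10.0, box_height_y=6.0,
                                   source_width=None, res_factor=15.0,
                                   theta_inc_deg=theta)
            fm = solve_scene(lens, 450.0, cfg, small_box)
            pj = characterize_pj(fm, lens.union.bounds)
            angles.append(pj.angle_deg)
        assert angles[1] - angles[0] > 5.0

    def test_jet_strengthens_with_contrast(self, small_config, small_box):
        peaks = []
        for n_v in (1.2, 1.46):
            lens = build_analytic_component("lens", {"width": 0.86, "D": 0.38,
                                                     "sag": 0.21},
                                            OpticalConstants(n_v, 1.0),
                                            face_x=4.0)
            fm = solve_scene(lens, 450.0, small_config, small_box)
            peaks.append(characterize_pj(fm, lens.union.bounds).E_Norm_PJ)
        assert peaks[1] > peaks[0]


@pytest.fixture(scope="module")
def grating_field():
    scene = build_analytic_component(
        "grid", {"d": 0.5, "ff": 0.7, "D": 0.17, "N": 11},
        OpticalConstants(), face_x=2.0)
    box = (0.0, -5.0, 9.0, 5.0)
    cfg = SimulationConfig(box_width_x=9.0, box_height_y=10.0,
                           source_width=None, res_factor=15.0)
    return scene, solve_scene(scene, 350.0, cfg, box)


class TestTalbot:
    def test_transverse_period_matches_grating_pitch(self, grating_field):
        scene, fm = grating_field
        t = extract_talbot(fm, 0.5, scene=scene)
        # profile through the first Talbot plane repeats with period d
        from frustulight.solver import cutline
        x_plane = t.plane_positions[0]
        prof = cutline(fm, (x_plane, -2.0), (x_plane, 2.0), 800)[:, 2]
        spectrum = np.abs(np.fft.rfft(prof - prof.mean()))
        freqs = np.fft.rfftfreq(800, d=4.0 / 800)
        assert 1.0 / freqs[np.argmax(spectrum)] == pytest.approx(0.5, rel=0.1)

    def test_scene_without_grid_is_rejected(self, grating_field):
        _, fm = grating_field
        bare = GeometryScene([], OpticalConstants(), "h", {"face_x": 2.0})
        with pytest.raises(FeatureError):
            extract_talbot(fm, 0.5, scene=bare)

    def test_too_small_domain_reports_extension_needed(self, small_config):
        scene = build_analytic_component(
            "grid", {"d": 0.5, "ff": 0.7, "D": 0.17, "N": 8},
            OpticalConstants(), face_x=2.0)
        box = (0.0, -3.0, 3.6, 3.0)   # < 2 Talbot lengths downstream
        cfg = SimulationConfig(box_width_x=3.6, box_height_y=6.0,
                               source_width=None, res_factor=15.0)
        fm = solve_scene(scene, 330.0, cfg, box)
        with pytest.raises(FeatureError, match="extend"):
            extract_talbot(fm, 0.5, scene=scene)


class TestGmrValidation:
    def test_window_outside_band_rejected(self, small_config):
        scene = build_analytic_component(
            "grid", {"d": 0.5, "ff": 0.7, "D": 0.17, "N": 8},
            OpticalConstants(), face_x=2.0)
        with pytest.raises(FeatureError):
            find_gmr(scene, (100.0, 200.0), small_config)

    def test_gridless_scene_rejected(self, small_config):
        scene = build_analytic_component("slab", {"L": 5.0, "D": 0.17},
                                         OpticalConstants(), face_x=2.0)
        with pytest.raises(FeatureError, match="grid"):
            find_gmr(scene, (500.0, 620.0), small_config)
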