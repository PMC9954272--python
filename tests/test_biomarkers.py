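import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sepscreen.biomarkers import (
    GeometryError,
    above_metrics,
    crossing_metrics,
    detect_crossing,
    extract_biomarkers,
    med_total,
    mee_first,
    met_first,
    metr_total,
    step_distance,
)
from sepscreen.scene import SceneConfig
from sepscreen.simulate import NC_PROFILE, random_profile, simulate_trial

from conftest import brute_extract, make_log

SR = 60.0


class TestStepDistance:
    def test_three_four_five(self):
        assert step_distance((0, 0), (3, 4)) == 5.0

    def test_identity(self):
        assert step_distance((10, 10), (10, 10)) == 0.0

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6), st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    @settings(derandomize=True, max_examples=50)
    def test_symmetric_and_nonnegative(self, x1, y1, x2, y2):
        d = step_distance((x1, y1), (x2, y2))
        assert d >= 0
        assert d == step_distance((x2, y2), (x1, y1))

    def test_random_walk_sum_matches_accumulation_loop(self):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(0, 5, (101, 2)), axis=0) + (1280, 500)
        total = sum(step_distance(tuple(pts[i]), tuple(pts[i + 1])) for i in range(100))
        log = make_log(pts)
        assert med_total(log) == pytest.approx(total, rel=1e-12)


class TestSingleMarkers:
    def test_metr_total_examples(self, scene):
        log = make_log(
            [(1280.0, 500.0)] * 3601,
            {"left": 1, "right": 2, "bottom": 3, "top": 3600},
        )
        assert metr_total(log) == pytest.approx(0.5)  # Te=60 of T=120
        incomplete = make_log([(1280.0, 500.0)] * 10)
        assert metr_total(incomplete) == 1.0

    def test_med_total_ten_345_steps(self):
        pts = [(3.0 * i + 100, 4.0 * i + 100) for i in range(11)]
        assert med_total(make_log(pts)) == pytest.approx(50.0)

    def test_stationary_sphere_travels_nothing(self):
        assert med_total(make_log([(500.0, 500.0)] * 50)) == 0.0

    def test_met_first_is_first_event_time(self):
        log = make_log([(1280.0, 500.0)] * 100, {"left": 67})
        assert met_first(log) == pytest.approx(67 / SR)

    def test_met_first_missing_without_events(self):
        assert met_first(make_log([(1280.0, 500.0)] * 10)) is None

    def test_mee_first_straight_approach_scores_one(self, scene):
        # straight constant-speed run from start onto the left cube's contact point
        sx, sy = scene.sphere_start
        cx, cy = scene.cube_centers["left"]
        d_contact = abs(cx - sx) - scene.contact_distance_px
        n = 200
        pts = [(sx - d_contact * i / n, sy) for i in range(n + 1)]
        log = make_log(pts, {"left": n})
        assert mee_first(log) == pytest.approx(1.0, abs=0.02)

    def test_mee_first_retraced_path_scores_two(self, scene):
        sx, sy = scene.sphere_start
        cx, _ = scene.cube_centers["left"]
        d_contact = abs(cx - sx) - scene.contact_distance_px
        half = d_contact / 2
        # out half-way, back, then all the way: 2x the shortest distance
        leg1 = [(sx - half * i / 100, sy) for i in range(101)]
        leg2 = [(sx - half + half * i / 100, sy) for i in range(1, 101)]
        leg3 = [(sx - d_contact * i / 200, sy) for i in range(1, 201)]
        pts = leg1 + leg2 + leg3
        log = make_log(pts, {"left": len(pts) - 1})
        assert mee_first(log) == pytest.approx(2.0, abs=0.02)

    def test_mee_first_degenerate_geometry(self, scene):
        cubes = dict(scene.cube_centers)
        cubes["left"] = (scene.sphere_start[0] - 50.0, scene.sphere_start[1])
        bad = dataclasses.replace(scene, cube_centers=cubes)
        log = make_log([(1280.0, 500.0)] * 5, {"left": 4})
        with pytest.raises(GeometryError, match="degenerate"):
            mee_first(log, bad)


class TestCrossing:
    def test_first_upward_crossing_detected(self, scene):
        ys = [800.0, 840.0, 860.0, 900.0]
        log = make_log([(1280.0, y) for y in ys])
        t, idx = detect_crossing(log)
        assert idx == 2  # the 840 -> 860 step crosses 850
        assert t == pytest.approx(2 / SR)

    def test_never_above_returns_none(self):
        log = make_log([(1280.0, 500.0 + i) for i in range(100)])
        assert detect_crossing(log) is None

    def test_oscillating_path_keeps_earliest_crossing(self):
        ys = [800.0, 900.0, 800.0, 900.0, 800.0, 900.0]
        log = make_log([(1280.0, y) for y in ys])
        _, idx = detect_crossing(log)
        assert idx == 1

    def test_crossing_metrics_arithmetic(self, scene):
        # crossing at sample 1200 (t=20), Te at sample 3000 (t=50)
        ys = [500.0] * 1200 + [900.0] * 1801
        log = make_log(
            [(1280.0, y) for y in ys],
            {"left": 100, "right": 200, "bottom": 300, "top": 3000},
        )
        et, ed = crossing_metrics(log)
        assert et == pytest.approx(30.0)
        assert ed == pytest.approx(0.0)  # stationary after crossing

    def test_crossing_at_final_instant_gives_zero_remainder(self, scene):
        ys = [500.0] * 100 + [900.0]
        log = make_log(
            [(1280.0, y) for y in ys],
            {"left": 10, "right": 20, "bottom": 30, "top": 100},
        )
        et, ed = crossing_metrics(log)
        assert et == 0.0
        assert ed == 0.0

    def test_no_crossing_gives_missing_crossing_metrics(self):
        log = make_log([(1280.0, 500.0)] * 50)
        assert crossing_metrics(log) == (None, None)


class TestAbove:
    def test_never_above_is_zero(self):
        et, ed = above_metrics(make_log([(1280.0, 500.0)] * 100))
        assert (et, ed) == (0.0, 0.0)

    def test_continuously_above_counts_steps(self, scene):
        # 600 above-obstacle steps at 60 Hz = 10 s of dwell
        ys = [500.0] + [900.0] * 601
        log = make_log([(1280.0, y) for y in ys])
        et, ed = above_metrics(log)
        assert et == pytest.approx(600 / SR)
        assert ed == 0.0

    def test_boundary_straddling_steps_excluded(self, scene):
        # alternate below/above: no step has both endpoints above
        ys = [840.0, 860.0] * 50
        log = make_log([(1280.0 + i, y) for i, y in enumerate(ys)])
        et, ed = above_metrics(log)
        assert et == 0.0
        assert ed == 0.0


class TestExtractor:
    def test_complete_trial_has_all_fields_and_invariants(self):
        log = simulate_trial(NC_PROFILE, seed=5)
        assert log.complete
        v = extract_biomarkers(log)
        assert all(
            getattr(v, f) is not None
            for f in (
                "metr_total",
                "met_first_s",
                "et_crossing_s",
                "et_above_s",
                "med_total_px",
                "mee_first",
                "ed_crossing_px",
                "ed_above_px",
                "crossing_t_s",
            )
        )
        assert 0 < v.metr_total <= 1
        assert v.et_above_s <= v.et_crossing_s + 1e-9
        assert v.ed_above_px <= v.ed_crossing_px + 1e-9
        assert v.ed_crossing_px <= v.med_total_px + 1e-9

    def test_trial_that_never_crosses(self):
        log = make_log([(1280.0, 500.0 + i * 0.1) for i in range(200)], {"left": 100})
        v = extract_biomarkers(log)
        assert v.et_crossing_s is None and v.ed_crossing_px is None
        assert v.crossing_t_s is None
        assert v.et_above_s == 0.0 and v.ed_above_px == 0.0

    def test_stationary_incomplete_trial(self):
        v = extract_biomarkers(make_log([(1280.0, 500.0)] * 100))
        assert v.metr_total == 1.0
        assert v.med_total_px == 0.0
        assert not v.complete
        assert v.met_first_s is None and v.mee_first is None

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        log = simulate_trial(random_profile(rng), seed=seed)
        v = extract_biomarkers(log)
        ref = brute_extract(log)
        for key, expected in ref.items():
            got = getattr(v, key)
            if expected is None:
                assert got is None
            elif isinstance(expected, bool):
                assert got == expected
            else:
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-9), key


class TestGeometryEquivariance:
    @staticmethod
    def _transform_scene(scene, shift=(0.0, 0.0), scale=1.0):
        dx, dy = shift
        cubes = {
            k: (scale * x + dx, scale * y + dy) for k, (x, y) in scene.cube_centers.items()
        }
        return dataclasses.replace(
            scene,
            screen_width_px=scale * scene.screen_width_px + abs(dx) + 1,
            screen_height_px=scale * scene.screen_height_px + abs(dy) + 1,
            sphere_start=(scale * scene.sphere_start[0] + dx, scale * scene.sphere_start[1] + dy),
            sphere_radius_px=scale * scene.sphere_radius_px,
            cube_centers=cubes,
            cube_half_size_px=scale * scene.cube_half_size_px,
            obstacle_y_px=scale * scene.obstacle_y_px + dy,
            obstacle_x_min_px=scale * scene.obstacle_x_min_px + dx,
            obstacle_x_max_px=scale * scene.obstacle_x_max_px + dx,
            obstacle_thickness_px=scale * scene.obstacle_thickness_px,
        )

    @pytest.mark.parametrize("shift,scale", [((137.5, -41.25), 1.0), ((0.0, 0.0), 2.5), ((61.0, 13.0), 0.5)])
    def test_translation_invariance_and_scaling_equivariance(self, shift, scale):
        log = simulate_trial(NC_PROFILE, seed=9)
        new_scene = self._transform_scene(log.scene, shift, scale)
        moved = dataclasses.replace(
            log,
            scene=new_scene,
            positions=log.positions * scale + np.asarray(shift),
        )
        v0 = extract_biomarkers(log)
        v1 = extract_biomarkers(moved)
        # time biomarkers unchanged
        for f in ("metr_total", "met_first_s", "et_crossing_s", "et_above_s", "crossing_t_s"):
            assert getattr(v1, f) == pytest.approx(getattr(v0, f), rel=1e-9)
        # distance biomarkers scale by s; the efficiency ratio is scale-free
        for f in ("med_total_px", "ed_crossing_px", "ed_above_px"):
            assert getattr(v1, f) == pytest.approx(scale * getattr(v0, f), rel=1e-9)
        assert v1.mee_first == pytest.approx(v0.mee_first, rel=1e-9)

    def test_time_reversal_maps_to_last_downward_crossing(self, scene):
        # symmetric up-and-back trajectory: reversing time maps the first
        # upward crossing onto the mirror position of the last downward one
        ys = [700.0 + 2.0 * i for i in range(150)] + [998.0 - 2.0 * i for i in range(150)]
        pts = [(1280.0, y) for y in ys]
        fwd = make_log(pts)
        rev = make_log(pts[::-1])
        f = detect_crossing(fwd)
        r = detect_crossing(rev)
        assert f is not None and r is not None
        n = len(pts)
        # mirrored indices: reversed-log crossing index = n-1 - (forward last-above index)
        y_arr = np.array(ys)
        last_above_fwd = np.flatnonzero(y_arr > fwd.scene.obstacle_y_px).max()
        assert r[1] == n - 1 - last_above_fwd
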