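import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retinagaze import (
    DisplayLayout,
    Fixation,
    TrackerAccuracy,
    Viewport,
    degrees_to_pixels,
    detect_fixations_idt,
    invalidate_zoom_transitions,
    remap_point,
    remap_to_image_coords,
    screen_to_region_fraction,
    track_length,
    zoom_level,
)
from retinagaze.geometry import GAZE_LOG_COLUMNS


def make_log(rows):
    return pd.DataFrame(rows, columns=GAZE_LOG_COLUMNS)


class TestRemap:
    @pytest.mark.parametrize(
        "frac, origin, size, expected",
        [
            ((0.5, 0.5), (200, 100), (50, 50), (225.0, 125.0)),
            ((0.0, 0.0), (0, 0), (640, 480), (0.0, 0.0)),
            ((0.25, 0.75), (100, 40), (80, 40), (120.0, 70.0)),
        ],
    )
    def test_viewport_remap(self, frac, origin, size, expected):
        vp = Viewport(origin[0], origin[1], size[0], size[1], zoom=1.0)
        assert remap_point(frac[0], frac[1], vp) == pytest.approx(expected)

    @given(
        px=st.floats(0, 1139),
        py=st.floats(0, 847),
        ox=st.floats(0, 500),
        oy=st.floats(0, 300),
        k=st.integers(0, 4),
    )
    def test_round_trip_recovers_image_point(self, px, py, ox, oy, k):
        """A fraction computed from a known image point remaps to that point."""
        z = zoom_level(k)
        vp = Viewport(ox, oy, 1140 / z, 848 / z, zoom=z)
        fx = (px - vp.origin_x) / vp.width
        fy = (py - vp.origin_y) / vp.height
        x, y = remap_point(fx, fy, vp)
        assert abs(x - px) < 0.5 and abs(y - py) < 0.5

    def test_zoom_invariance_of_fixed_feature(self):
        """Gaze locked on one image feature remaps identically at every zoom."""
        feature = (512.0, 300.0)
        out = set()
        for k in range(5):
            z = zoom_level(k)
            vp = Viewport(
                min(feature[0], 1140 - 1140 / z),
                min(feature[1], 848 - 848 / z),
                1140 / z,
                848 / z,
                zoom=z,
            )
            fx = (feature[0] - vp.origin_x) / vp.width
            fy = (feature[1] - vp.origin_y) / vp.height
            out.add(tuple(round(c, 6) for c in remap_point(fx, fy, vp)))
        assert out == {feature}

    def test_invalid_samples_get_nan(self):
        log = make_log(
            [
                (0.0, 0.5, 0.5, True, 1.0, 200, 100, 50, 50),
                (10.0, 0.5, 0.5, False, 1.0, 200, 100, 50, 50),
            ]
        )
        out = remap_to_image_coords(log)
        assert out.loc[0, "x"] == 225.0 and out.loc[0, "y"] == 125.0
        assert np.isnan(out.loc[1, "x"]) and np.isnan(out.loc[1, "y"])

    def test_viewport_outside_image_flags_corrupt_log(self):
        log = make_log([(0.0, 0.5, 0.5, True, 1.0, 1100, 100, 100, 50)])
        with pytest.raises(ValueError, match="corrupt"):
            remap_to_image_coords(log, image_width=1140, image_height=848)


class TestInvalidation:
    @staticmethod
    def log_with_change(times, change_at=1000.0):
        rows = []
        for t in times:
            zoom = 1.0 if t < change_at else 1.5
            rows.append((t, 0.5, 0.5, True, zoom, 0, 0, 1140 / zoom, 848 / zoom))
        return make_log(rows)

    def test_sample_inside_window_invalidated(self):
        log = self.log_with_change([900.0, 1000.0, 1150.0, 1300.0])
        out, n = invalidate_zoom_transitions(log, window_ms=200.0)
        assert list(out["valid"]) == [True, False, False, True]
        assert n == 2

    def test_no_changes_is_a_no_op(self):
        log = make_log([(t, 0.5, 0.5, True, 1.0, 0, 0, 1140, 848) for t in (0.0, 10.0)])
        out, n = invalidate_zoom_transitions(log)
        assert n == 0 and out["valid"].all()

    def test_closed_interval_boundary(self):
        """Window [t_change, t_change + 200] includes both endpoints."""
        log = self.log_with_change([990.0, 1000.0, 1200.0, 1201.0])
        out, _ = invalidate_zoom_transitions(log, window_ms=200.0)
        assert list(out["valid"]) == [True, False, False, True]

    def test_two_sided_window_also_covers_pre_change(self):
        log = self.log_with_change([750.0, 990.0, 1000.0, 1300.0])
        out, _ = invalidate_zoom_transitions(log, window_ms=200.0, two_sided=True)
        assert list(out["valid"]) == [True, False, False, True]

    @given(windows=st.lists(st.floats(0, 600), min_size=2, max_size=6))
    def test_invalidated_count_monotone_in_window(self, windows):
        log = self.log_with_change(np.arange(0.0, 2000.0, 50.0))
        counts = [invalidate_zoom_transitions(log, w)[1] for w in sorted(windows)]
        assert counts == sorted(counts)

    def test_empty_log(self):
        out, n = invalidate_zoom_transitions(make_log([]))
        assert len(out) == 0 and n == 0


class TestAccuracyConversion:
    def test_zero_angle_is_zero_pixels(self):
        acc = TrackerAccuracy(accuracy_deg=0.0)
        assert degrees_to_pixels(acc) == 0.0

    def test_tangent_formula(self):
        # independent evaluation of d*tan(theta)/pitch
        acc = TrackerAccuracy(accuracy_deg=1.0, viewing_distance_mm=600, pixel_pitch_mm=0.2744)
        expected = 600 * math.tan(math.radians(1.0)) / 0.2744
        assert degrees_to_pixels(acc) == pytest.approx(expected)
        assert degrees_to_pixels(acc) == pytest.approx(38.2, abs=0.1)

    def test_default_accuracy_is_not_the_operational_radius(self):
        """The tangent formula gives ~61 px for the default accuracy; the
        70 px expansion radius is an operational choice kept separate."""
        acc = TrackerAccuracy()
        assert degrees_to_pixels(acc) == pytest.approx(60.7, abs=0.1)
        assert acc.expansion_radius_px == 70.0

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            degrees_to_pixels(TrackerAccuracy(pixel_pitch_mm=0.0))
        with pytest.raises(ValueError):
            degrees_to_pixels(TrackerAccuracy(viewing_distance_mm=-1.0))


def stationary_log(x, y, t0=0.0, n=30, dt=10.0, valid=True):
    rows = [
        (t0 + i * dt, 0.0, 0.0, valid, 1.0, 0, 0, 1140, 848) for i in range(n)
    ]
    log = make_log(rows)
    log["x"] = x
    log["y"] = y
    return log


class TestIDT:
    def test_stationary_gaze_is_one_fixation(self):
        log = stationary_log(100.0, 200.0, n=30, dt=10.0)
        fixations = detect_fixations_idt(log, 70.0, 100.0)
        assert len(fixations) == 1
        f = fixations[0]
        assert (f.x, f.y) == (100.0, 200.0)
        assert f.duration == pytest.approx(300.0)

    def test_two_separated_clusters_are_two_fixations(self):
        a = stationary_log(100.0, 100.0, t0=0.0, n=20, dt=10.0)
        b = stationary_log(600.0, 100.0, t0=200.0, n=20, dt=10.0)
        log = pd.concat([a, b], ignore_index=True)
        fixations = detect_fixations_idt(log, 70.0, 100.0)
        assert len(fixations) == 2
        assert fixations[0].x == pytest.approx(100.0)
        assert fixations[1].x == pytest.approx(600.0)

    def test_short_burst_below_min_duration_is_dropped(self):
        log = stationary_log(100.0, 100.0, n=5, dt=10.0)  # 50 ms
        assert detect_fixations_idt(log, 70.0, 100.0) == []

    def test_all_invalid_input_yields_nothing(self):
        log = stationary_log(100.0, 100.0, n=30, valid=False)
        assert detect_fixations_idt(log, 70.0, 100.0) == []

    def test_invalid_sample_breaks_a_window(self):
        a = stationary_log(100.0, 100.0, t0=0.0, n=15, dt=10.0)
        gap = stationary_log(100.0, 100.0, t0=150.0, n=1, dt=10.0, valid=False)
        b = stationary_log(100.0, 100.0, t0=160.0, n=15, dt=10.0)
        log = pd.concat([a, gap, b], ignore_index=True)
        fixations = detect_fixations_idt(log, 70.0, 100.0)
        assert len(fixations) == 2


class TestTrackLength:
    def test_fewer_than_two_fixations(self):
        assert track_length([]) == 0.0
        assert track_length([Fixation(1, 2, 0, 100)]) == 0.0

    def test_pythagorean_pair(self):
        fx = [Fixation(0, 0, 0, 100), Fixation(3, 4, 100, 100)]
        assert track_length(fx) == pytest.approx(5.0)

    def test_open_square_path(self):
        pts = [(0, 0), (10, 0), (10, 10), (0, 10)]
        fx = [Fixation(x, y, 100 * i, 100) for i, (x, y) in enumerate(pts)]
        assert track_length(fx) == pytest.approx(30.0)

    @given(
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
        scale=st.floats(0.1, 10),
    )
    def test_translation_invariant_and_scale_linear(self, dx, dy, scale):
        pts = [(0.0, 0.0), (30.0, 40.0), (90.0, 40.0), (10.0, 120.0)]
        base = track_length([Fixation(x, y, i, 1) for i, (x, y) in enumerate(pts)])
        shifted = track_length(
            [Fixation(x + dx, y + dy, i, 1) for i, (x, y) in enumerate(pts)]
        )
        scaled = track_length(
            [Fixation(x * scale, y * scale, i, 1) for i, (x, y) in enumerate(pts)]
        )
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-6)
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-6)


class TestDisplayLayout:
    def test_defaults_tile_the_native_screen(self):
        layout = DisplayLayout()
        assert layout.border_left + layout.region_width + layout.border_right == 1920
        assert layout.border_top + layout.region_height + layout.border_bottom == 1080

    def test_inconsistent_borders_rejected(self):
        with pytest.raises(ValueError):
            DisplayLayout(border_left=100)

    def test_screen_pixel_conversion(self):
        layout = DisplayLayout()
        # centre of the display region
        fx, fy = screen_to_region_fraction(390 + 570, 222 + 424, layout)
        assert (fx, fy) == pytest.approx((0.5, 0.5))
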