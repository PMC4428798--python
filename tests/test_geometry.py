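import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from harbourcam.errors import ConfigurationError, DataError, PositioningError
from harbourcam.geo import LocalFrame, polar_to_xy
from harbourcam.geometry import (
    depression_to_range,
    estimate_position,
    pixel_to_bearing,
    pixel_to_degrees_still,
    pixel_to_degrees_video,
    project_forward,
)
from harbourcam.rig import CameraRig, Landmark
from harbourcam.tide import TideSeries, effective_height


def _simple_rig(**over):
    """Minimal hand-built rig: two plain landmarks, flat wharf at 300 m."""
    kw = dict(
        camera_id="t",
        lat=-32.0,
        lon=115.75,
        height_above_datum=5.0,
        image_width=1000,
        image_height=800,
        landmarks=[
            Landmark("a", 250.0, 200.0),
            Landmark("b", 260.0, 700.0),
        ],
        wharf_profile=[(240.0, 300.0), (270.0, 300.0)],
        horizon_points=[(0.0, 200.0), (999.0, 200.0)],
    )
    kw.update(over)
    return CameraRig(**kw)


def _flat_tide(level=0.0):
    t = pd.date_range("2010-05-01", periods=10, freq="h")
    return TideSeries(pd.DataFrame({"timestamp": t, "level_m": level}))


class TestBearingInterpolation:
    def test_landmark_node_identity_and_midpoint(self):
        rig = _simple_rig()
        assert pixel_to_bearing(rig, 200.0) == pytest.approx(250.0)
        assert pixel_to_bearing(rig, 700.0) == pytest.approx(260.0)
        # midway between landmarks at 250 and 260 degrees
        assert pixel_to_bearing(rig, 450.0) == pytest.approx(255.0)

    def test_against_two_point_line_oracle(self):
        rig = _simple_rig()
        rng = np.random.default_rng(0)
        for col in rng.uniform(0, 999, 50):
            # independent two-point line through the landmark pairs
            expected = 250.0 + (260.0 - 250.0) * (col - 200.0) / (700.0 - 200.0)
            assert pixel_to_bearing(rig, col) == pytest.approx(expected % 360, abs=1e-9)

    def test_extrapolation_is_flagged(self):
        rig = _simple_rig()
        assert rig.bearing_is_extrapolated(100.0)
        assert not rig.bearing_is_extrapolated(400.0)

    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            _simple_rig(landmarks=[Landmark("a", 250.0, 200.0)])
        with pytest.raises(ConfigurationError):
            _simple_rig(
                landmarks=[
                    Landmark("a", 250.0, 200.0),
                    Landmark("b", 255.0, 500.0),
                    Landmark("c", 252.0, 700.0),  # not monotone
                ]
            )

    @given(col=st.floats(min_value=200.0, max_value=700.0))
    @settings(max_examples=50, derandomize=True)
    def test_order_preserving_between_nodes(self, col):
        rig = _simple_rig()
        b = pixel_to_bearing(rig, col)
        assert 250.0 <= b <= 260.0


class TestEffectiveHeight:
    def test_zero_tide_identity(self):
        rig = _simple_rig()
        assert effective_height(rig, _flat_tide(0.0), "2010-05-01 03:00") == pytest.approx(5.0)

    def test_arithmetic(self):
        rig = _simple_rig(height_above_datum=3.0)
        assert effective_height(rig, _flat_tide(0.8), "2010-05-01 03:00") == pytest.approx(2.2)

    def test_interpolation_matches_oracle(self):
        t = pd.to_datetime(["2010-05-01 00:00", "2010-05-01 01:00"])
        tide = TideSeries(pd.DataFrame({"timestamp": t, "level_m": [0.2, 0.8]}))
        q = pd.Timestamp("2010-05-01 00:24")
        frac = 24 / 60
        expected = 0.2 + frac * (0.8 - 0.2)
        assert tide.level_at(q) == pytest.approx(expected, abs=1e-12)

    def test_submerged_camera_is_data_error(self):
        rig = _simple_rig(height_above_datum=0.5)
        with pytest.raises(DataError):
            effective_height(rig, _flat_tide(0.9), "2010-05-01 03:00")

    def test_outside_series_beyond_tolerance(self):
        with pytest.raises(DataError):
            _flat_tide().level_at("2010-05-02 12:00")


class TestPixelToDegrees:
    def test_still_axis_identity_and_tan45(self):
        rig = _simple_rig(focal_length_mm=5.0, pixel_pitch_mm=0.002)
        assert pixel_to_degrees_still(rig, 0.0) == 0.0
        # offset * pitch == focal  ->  45 degrees
        assert pixel_to_degrees_still(rig, 2500.0) == pytest.approx(45.0)
        assert pixel_to_degrees_still(rig, -2500.0) == pytest.approx(-45.0)

    def test_still_small_angle_limit(self):
        rig = _simple_rig(focal_length_mm=5.0, pixel_pitch_mm=0.002)
        for off in (10.0, 50.0, 150.0, 215.0):  # < 5 degrees
            exact = pixel_to_degrees_still(rig, off)
            approx = math.degrees(off * 0.002 / 5.0)
            assert abs(exact) < 5.0
            assert exact == pytest.approx(approx, rel=0.005)

    def test_still_requires_focal_metadata(self):
        with pytest.raises(ConfigurationError):
            pixel_to_degrees_still(_simple_rig(), 10.0)

    def test_video_scale_self_consistency(self):
        # one light of known height: querying its own pixel span must return
        # exactly its angular span
        h, dist, h_lm = 5.0, 300.0, 12.0
        span = math.degrees(math.atan(h / dist) + math.atan((h_lm - h) / dist))
        k = 80.0
        lms = [
            Landmark("light", 255.0, 450.0, pixel_row_top=300.0 - k, pixel_row_base=300.0, physical_height=h_lm),
            Landmark("b", 260.0, 700.0),
        ]
        rig = _simple_rig(landmarks=lms)
        assert pixel_to_degrees_video(rig, k) == pytest.approx(span)

    def test_video_mean_of_equal_scales(self):
        h, dist, h_lm = 5.0, 300.0, 12.0
        span = math.degrees(math.atan(h / dist) + math.atan((h_lm - h) / dist))
        k = 64.0
        lms = [
            Landmark("l1", 252.0, 300.0, pixel_row_top=300.0 - k, pixel_row_base=300.0, physical_height=h_lm),
            Landmark("l2", 258.0, 600.0, pixel_row_top=310.0 - k, pixel_row_base=310.0, physical_height=h_lm),
        ]
        rig = _simple_rig(landmarks=lms)
        assert rig.video_row_scale() == pytest.approx(span / k)

    def test_video_requires_height_calibration(self):
        with pytest.raises(ConfigurationError):
            pixel_to_degrees_video(_simple_rig(), 10.0)

    def test_video_scale_recovers_forward_model(self, video_rig, small_cfg):
        assert video_rig.video_row_scale() == pytest.approx(
            small_cfg.video_row_scale_deg, rel=0.01
        )


class TestDepressionToRange:
    def test_tan45(self):
        assert depression_to_range(2.5, 45.0) == pytest.approx(2.5)

    def test_at_horizon_is_positioning_error(self):
        with pytest.raises(PositioningError):
            depression_to_range(2.5, 0.0)

    def test_pixel_on_wharf_line_returns_wharf_distance(self, video_rig, tide, mid_time):
        col = 700.0
        row = video_rig.horizon_row(col)
        est = estimate_position(
            video_rig,
            {"obs_id": "w", "timestamp": mid_time, "pixel_col": col, "pixel_row": row},
            tide,
        )
        assert est.range_m == pytest.approx(
            video_rig.wharf_distance(video_rig.bearing_at_col(col)), rel=1e-9
        )

    def test_forward_inverse_roundtrip(self, video_rig, tide, mid_time, haversine):
        frame = LocalFrame(video_rig.lat, video_rig.lon)
        rng = np.random.default_rng(1)
        for _ in range(50):
            b = rng.uniform(250, 295)
            r = rng.uniform(15, 0.9 * video_rig.wharf_distance(b))
            x, y = polar_to_xy(r, b)
            lat, lon = frame.to_latlon(float(x), float(y))
            proj = project_forward(video_rig, float(lat), float(lon), tide, mid_time)
            assert proj.in_view
            est = estimate_position(
                video_rig,
                {
                    "obs_id": "r",
                    "timestamp": mid_time,
                    "pixel_col": proj.pixel_col,
                    "pixel_row": proj.pixel_row,
                },
                tide,
            )
            assert abs(est.range_m - r) < 0.01
            assert haversine(est.lat, est.lon, lat, lon) < 0.01


class TestEstimatePosition:
    def test_due_north_matches_haversine(self, haversine):
        frame = LocalFrame(-32.0, 115.75)
        x, y = polar_to_xy(100.0, 0.0)
        lat, lon = frame.to_latlon(float(x), float(y))
        d = haversine(-32.0, 115.75, float(lat), float(lon))
        assert abs(d - 100.0) < 0.05
        assert float(lon) == pytest.approx(115.75, abs=1e-9)
        assert float(lat) > -32.0

    def test_due_east_displaces_longitude_only(self):
        frame = LocalFrame(-32.0, 115.75)
        x, y = polar_to_xy(150.0, 90.0)
        lat, lon = frame.to_latlon(float(x), float(y))
        assert float(lat) == pytest.approx(-32.0, abs=1e-7)
        assert float(lon) > 115.75

    def test_estimate_bearing_matches_due_landmark(self, video_rig, tide, mid_time):
        lm = video_rig.landmarks[1]
        est = estimate_position(
            video_rig,
            {
                "obs_id": "lm",
                "timestamp": mid_time,
                "pixel_col": lm.pixel_col,
                "pixel_row": video_rig.horizon_row(lm.pixel_col) + 40.0,
            },
            tide,
        )
        assert est.bearing_true == pytest.approx(lm.bearing_true, abs=1e-9)

    def test_above_horizon_raises(self, video_rig, tide, mid_time):
        col = 700.0
        row = video_rig.horizon_row(col) - 10.0
        with pytest.raises(PositioningError):
            estimate_position(
                video_rig,
                {"obs_id": "h", "timestamp": mid_time, "pixel_col": col, "pixel_row": row},
                tide,
            )

    def test_invariant_range_tan_depression_equals_height(self, video_rig, tide, mid_time):
        est = estimate_position(
            video_rig,
            {"obs_id": "i", "timestamp": mid_time, "pixel_col": 700.0, "pixel_row": 500.0},
            tide,
        )
        assert est.range_m * math.tan(math.radians(est.depression_angle)) == pytest.approx(
            est.effective_camera_height, rel=1e-9
        )


class TestMonotonicityAndTide:
    def test_range_decreases_as_row_moves_down(self, video_rig, tide, mid_time):
        col = 700.0
        rows = np.linspace(video_rig.horizon_row(col) + 5, video_rig.image_height - 5, 20)
        ranges = [
            estimate_position(
                video_rig,
                {"obs_id": "m", "timestamp": mid_time, "pixel_col": col, "pixel_row": r},
                tide,
            ).range_m
            for r in rows
        ]
        assert all(a > b for a, b in zip(ranges, ranges[1:]))

    def test_raising_water_level_shrinks_height_and_range(self):
        rig = _simple_rig()
        delta = 0.3
        h1 = effective_height(rig, _flat_tide(0.2), "2010-05-01 03:00")
        h2 = effective_height(rig, _flat_tide(0.2 + delta), "2010-05-01 03:00")
        assert h1 - h2 == pytest.approx(delta, abs=1e-12)
        assert depression_to_range(h2, 1.5) < depression_to_range(h1, 1.5)

    def test_positioning_error_grows_with_range_under_pixel_noise(self, video_rig, tide, mid_time, haversine):
        rng = np.random.default_rng(2)
        frame = LocalFrame(video_rig.lat, video_rig.lon)

        def median_err(r):
            b = 293.0  # a bearing whose wharf distance exceeds the far stratum
            x, y = polar_to_xy(r, b)
            lat, lon = frame.to_latlon(float(x), float(y))
            proj = project_forward(video_rig, float(lat), float(lon), tide, mid_time)
            errs = []
            for _ in range(200):
                est = estimate_position(
                    video_rig,
                    {
                        "obs_id": "n",
                        "timestamp": mid_time,
                        "pixel_col": proj.pixel_col + rng.normal(0, 1),
                        "pixel_row": max(
                            proj.pixel_row + rng.normal(0, 1),
                            video_rig.horizon_row(proj.pixel_col) + 0.05,
                        ),
                    },
                    tide,
                )
                errs.append(haversine(est.lat, est.lon, lat, lon))
            return float(np.median(errs))

        assert median_err(50.0) <= median_err(400.0)


class TestProjectForward:
    def test_landmark_bearing_maps_to_landmark_column(self, video_rig, tide, mid_time):
        lm = video_rig.landmarks[2]
        frame = LocalFrame(video_rig.lat, video_rig.lon)
        x, y = polar_to_xy(100.0, lm.bearing_true)
        lat, lon = frame.to_latlon(float(x), float(y))
        proj = project_forward(video_rig, float(lat), float(lon), tide, mid_time)
        assert proj.in_view
        assert proj.pixel_col == pytest.approx(lm.pixel_col, abs=0.5)

    def test_point_on_wharf_waterline_hits_horizon_row(self, video_rig, tide, mid_time):
        b = 272.0
        # a point on the waterline would be at the wharf distance; step just
        # inside so the depression stays positive
        r = video_rig.wharf_distance(b) * (1 - 1e-9)
        frame = LocalFrame(video_rig.lat, video_rig.lon)
        x, y = polar_to_xy(r, b)
        lat, lon = frame.to_latlon(float(x), float(y))
        proj = project_forward(video_rig, float(lat), float(lon), tide, mid_time)
        assert proj.pixel_row == pytest.approx(video_rig.horizon_row(proj.pixel_col), abs=0.01)

    def test_beyond_wharf_is_out_of_view(self, video_rig, tide, mid_time):
        b = 272.0
        r = video_rig.wharf_distance(b) + 50.0
        frame = LocalFrame(video_rig.lat, video_rig.lon)
        x, y = polar_to_xy(r, b)
        lat, lon = frame.to_latlon(float(x), float(y))
        proj = project_forward(video_rig, float(lat), float(lon), tide, mid_time)
        assert not proj.in_view

    @given(
        height=st.floats(min_value=3.0, max_value=25.0),
        r_frac=st.floats(min_value=0.05, max_value=0.95),
        bearing=st.floats(min_value=251.0, max_value=293.0),
        level=st.floats(min_value=-0.5, max_value=1.0),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_roundtrip_property_over_randomized_rigs(self, height, r_frac, bearing, level, haversine):
        from harbourcam.simulate import SimulationConfig, simulate_scene

        cfg = SimulationConfig(seed=11, height_above_datum=height, block1_days=2, block2_days=1)
        rig = simulate_scene(cfg).rig
        tide = _flat_tide(level)
        t = "2010-05-01 03:00"
        r = r_frac * rig.wharf_distance(bearing)
        if r < 5.0:
            return
        frame = LocalFrame(rig.lat, rig.lon)
        x, y = polar_to_xy(r, bearing)
        lat, lon = frame.to_latlon(float(x), float(y))
        proj = project_forward(rig, float(lat), float(lon), tide, t)
        if not proj.in_view:
            return
        est = estimate_position(
            rig,
            {"obs_id": "p", "timestamp": t, "pixel_col": proj.pixel_col, "pixel_row": proj.pixel_row},
            tide,
        )
        assert haversine(est.lat, est.lon, lat, lon) < 0.1
        back = project_forward(rig, est.lat, est.lon, tide, t)
        assert back.pixel_col == pytest.approx(proj.pixel_col, abs=0.5)
        assert back.pixel_row == pytest.approx(proj.pixel_row, abs=0.5)
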