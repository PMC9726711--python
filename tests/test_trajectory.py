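"""Waypoint resampling and the questionnaire completeness filter."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tedrecon.trajectory import (
    ExposureWindow,
    MicroEnv,
    PersonRecord,
    Waypoint,
    position_at,
    read_waypoint_csv,
    resample_waypoints,
    validate_track,
    write_waypoint_csv,
)

from conftest import make_waypoint


class TestExposureWindow:
    def test_fixed_march_window_has_330_hours(self, window):
        assert window.start == datetime(2011, 3, 12, 6, 0)
        assert window.end == datetime(2011, 3, 26, 0, 0)
        assert window.n_hours == 330

    def test_hour_indexing_is_one_based_and_half_open(self, window):
        assert window.hour_index_of(window.start) == 1
        assert window.hour_index_of(window.start + timedelta(minutes=59)) == 1
        assert window.hour_index_of(window.start + timedelta(hours=1)) == 2
        with pytest.raises(IndexError):
            window.hour_index_of(window.end)


class TestResample:
    def test_stationary_person_holds_position_all_330_hours(self, window):
        wp = Waypoint(window.start, 37.56, 140.89, MicroEnv.INDOOR)
        track = resample_waypoints([wp], window, person_id="p", age_years=1)
        assert len(track) == 330
        assert np.all(track.latitudes == 37.56)
        assert np.all(track.longitudes == 140.89)
        assert all(e is MicroEnv.INDOOR for e in track.micro_env)

    def test_segment_midpoint_is_coordinate_midpoint(self):
        # constant-speed straight line: halfway in time = halfway in space
        a = Waypoint(datetime(2011, 3, 14, 12, 0), 37.0, 140.0)
        b = Waypoint(datetime(2011, 3, 14, 16, 0), 38.0, 141.0)
        assert position_at([a, b], datetime(2011, 3, 14, 14, 0)) == (37.5, 140.5)

    def test_segment_endpoint_identity(self):
        a = Waypoint(datetime(2011, 3, 14, 12, 0), 37.0, 140.0)
        b = Waypoint(datetime(2011, 3, 14, 16, 0), 38.0, 141.0)
        assert position_at([a, b], datetime(2011, 3, 14, 16, 0)) == (38.0, 141.0)

    def test_hours_outside_record_hold_endpoint_positions(self, window):
        wps = [
            make_waypoint(window, 100, 37.0, 140.0),
            make_waypoint(window, 104, 38.0, 141.0),
        ]
        track = resample_waypoints(wps, window)
        assert (track.latitudes[0], track.longitudes[0]) == (37.0, 140.0)
        assert (track.latitudes[-1], track.longitudes[-1]) == (38.0, 141.0)

    def test_travel_segment_hours_are_vehicle(self, window):
        wps = [
            make_waypoint(window, 0, 37.0, 140.0, MicroEnv.INDOOR),
            make_waypoint(window, 100, 37.0, 140.0, MicroEnv.INDOOR),
            make_waypoint(window, 110, 38.0, 141.0, MicroEnv.INDOOR),
            make_waypoint(window, 330, 38.0, 141.0, MicroEnv.INDOOR),
        ]
        track = resample_waypoints(wps, window)
        # hour 105 (mid 104:30) lies strictly inside the moving segment
        assert track.micro_env[104] is MicroEnv.VEHICLE
        assert track.micro_env[50] is MicroEnv.INDOOR
        assert track.micro_env[200] is MicroEnv.INDOOR

    def test_unknown_environment_defaults_to_indoor(self, window):
        wp = Waypoint(window.start, 37.5, 140.5, MicroEnv.UNKNOWN)
        track = resample_waypoints([wp], window)
        assert all(e is MicroEnv.INDOOR for e in track.micro_env)

    def test_resampling_is_idempotent(self, window):
        wps = [
            make_waypoint(window, 0, 37.0, 140.0),
            make_waypoint(window, 120, 37.0, 140.0),
            make_waypoint(window, 130, 37.8, 140.9, MicroEnv.OUTDOOR),
            make_waypoint(window, 330, 37.8, 140.9, MicroEnv.OUTDOOR),
        ]
        track = resample_waypoints(wps, window, person_id="p", age_years=4)
        again = resample_waypoints(
            track.to_waypoints(), window, person_id="p", age_years=4
        )
        np.testing.assert_array_equal(track.latitudes, again.latitudes)
        np.testing.assert_array_equal(track.longitudes, again.longitudes)
        assert track.micro_env == again.micro_env

    def test_empty_waypoints_is_hard_error(self, window):
        with pytest.raises(ValueError, match="empty"):
            resample_waypoints([], window, person_id="p77")

    def test_unordered_timestamps_error_names_person(self, window):
        wps = [make_waypoint(window, 10, 37.0, 140.0), make_waypoint(window, 5, 37.0, 140.0)]
        with pytest.raises(ValueError, match="p42"):
            resample_waypoints(wps, window, person_id="p42")

    @given(
        frac=st.floats(0.0, 1.0),
        lat1=st.floats(36.0, 38.0),
        lat2=st.floats(36.0, 38.0),
        lon1=st.floats(140.0, 141.0),
        lon2=st.floats(140.0, 141.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_interpolation_is_convex_combination(self, frac, lat1, lat2, lon1, lon2):
        t0 = datetime(2011, 3, 14, 0, 0)
        t1 = t0 + timedelta(hours=10)
        wps = [Waypoint(t0, lat1, lon1), Waypoint(t1, lat2, lon2)]
        t = t0 + timedelta(hours=10 * frac)
        lat, lon = position_at(wps, t)
        assert min(lat1, lat2) - 1e-9 <= lat <= max(lat1, lat2) + 1e-9
        assert min(lon1, lon2) - 1e-9 <= lon <= max(lon1, lon2) + 1e-9

    @given(n_wp=st.integers(1, 6))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_track_length_is_always_330(self, n_wp):
        window = ExposureWindow()
        rng = np.random.default_rng(n_wp)
        hours = np.sort(rng.uniform(0, 330, size=n_wp))
        hours = np.unique(hours)
        wps = [make_waypoint(window, float(h), 37.0 + 0.001 * i, 140.0) for i, h in enumerate(hours)]
        assert len(resample_waypoints(wps, window)) == 330


class TestValidate:
    def test_full_coverage_accepted(self, window):
        wps = [
            Waypoint(datetime(2011, 3, 11, 8, 0), 37.0, 140.0),
            Waypoint(datetime(2011, 3, 26, 8, 0), 37.0, 140.0),
        ]
        assert validate_track(wps, window).accepted

    def test_record_ending_20_march_excluded(self, window):
        wps = [
            Waypoint(datetime(2011, 3, 11, 8, 0), 37.0, 140.0),
            Waypoint(datetime(2011, 3, 20, 8, 0), 37.0, 140.0),
        ]
        verdict = validate_track(wps, window)
        assert not verdict.accepted
        assert verdict.reason == "incomplete_window"

    def test_unknown_whereabouts_gap_excluded(self, window):
        wps = [
            Waypoint(datetime(2011, 3, 11, 8, 0), 37.0, 140.0),
            Waypoint(datetime(2011, 3, 15, 8, 0), None, None),  # whereabouts unknown 15-17 March
            Waypoint(datetime(2011, 3, 17, 8, 0), 37.0, 140.0),
            Waypoint(datetime(2011, 3, 26, 8, 0), 37.0, 140.0),
        ]
        verdict = validate_track(wps, window)
        assert not verdict.accepted
        assert verdict.reason == "unknown_whereabouts"

    def test_single_waypoint_reads_as_stated_stay(self, window):
        assert validate_track([Waypoint(datetime(2011, 3, 13), 37.0, 140.0)], window).accepted

    def test_validation_never_raises(self, window):
        assert validate_track([], window).reason == "no_waypoints"
        wps = [
            Waypoint(datetime(2011, 3, 13), 37.0, 140.0),
            Waypoint(datetime(2011, 3, 12), 37.0, 140.0),
        ]
        assert validate_track(wps, window).reason == "unordered_timestamps"


class TestIO:
    def test_waypoint_csv_round_trip(self, tmp_path, window):
        records = [
            PersonRecord(
                "a1",
                3,
                [
                    make_waypoint(window, 0, 37.1, 140.2, MicroEnv.OUTDOOR),
                    make_waypoint(window, 330, 37.3, 140.4),
                ],
                municipality="town_x",
            ),
            PersonRecord("b2", 11, [Waypoint(window.start, None, None)], municipality="town_y"),
        ]
        path = tmp_path / "wp.csv"
        write_waypoint_csv(records, path)
        back = read_waypoint_csv(path)
        assert [r.person_id for r in back] == ["a1", "b2"]
        assert back[0].age_years == 3
        assert back[0].municipality == "town_x"
        assert back[0].waypoints[0].micro_environment is MicroEnv.OUTDOOR
        assert back[0].waypoints[1].latitude == 37.3
        assert not back[1].waypoints[0].has_position

    def test_track_csv_round_trip(self, tmp_path, window):
        from tedrecon.trajectory import read_track_csv, write_track_csv

        wp = Waypoint(window.start, 37.56, 140.89, MicroEnv.INDOOR)
        track = resample_waypoints([wp], window, person_id="p", age_years=1)
        path = tmp_path / "track.csv"
        write_track_csv(track, path)
        back = read_track_csv(path, person_id="p", age_years=1)
        np.testing.assert_array_equal(back.latitudes, track.latitudes)
        assert back.micro_env == track.micro_env
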