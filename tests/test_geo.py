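import math

import numpy as np
import pytest

import homingchains as hc
from homingchains.geo import TrajectoryFormatError, TrajectoryValidationError, utm_zone


def haversine_m(lat1, lon1, lat2, lon2, r=6371008.8):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def local_ellipsoid_m(lat1, lon1, lat2, lon2):
    """Flat-earth ellipsoidal oracle: ds^2 = (M dphi)^2 + (N cos(phi) dlam)^2."""
    a, f = 6378137.0, 1 / 298.257223563
    e2 = f * (2 - f)
    phi = math.radians(0.5 * (lat1 + lat2))
    s = math.sin(phi)
    M = a * (1 - e2) / (1 - e2 * s * s) ** 1.5
    N = a / math.sqrt(1 - e2 * s * s)
    dy = M * math.radians(lat2 - lat1)
    dx = N * math.cos(phi) * math.radians(lon2 - lon1)
    return math.hypot(dx, dy)


class TestTrajectory:
    def test_validation_rejects_duplicate_times(self):
        with pytest.raises(TrajectoryValidationError):
            hc.Trajectory([0.0, 1.0, 1.0], [0.0, 1.0, 2.0], [0.0, 1.0, 2.0])

    def test_validation_rejects_single_point_and_nan(self):
        with pytest.raises(TrajectoryValidationError):
            hc.Trajectory([0.0], [0.0], [0.0])
        with pytest.raises(TrajectoryValidationError):
            hc.Trajectory([0.0, 1.0], [0.0, np.nan], [0.0, 1.0])

    def test_path_length_sums_segments(self, zigzag):
        expected = sum(
            math.dist((zigzag.x[i], zigzag.y[i]), (zigzag.x[i + 1], zigzag.y[i + 1]))
            for i in range(zigzag.n_points - 1)
        )
        assert zigzag.path_length() == pytest.approx(expected, rel=1e-12)


class TestCsvIO:
    def test_planar_csv_parse(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("time_s,x_m,y_m\n0,0,8400\n1,0,8380\n")
        traj = hc.read_trajectory(p)
        assert traj.n_points == 2
        assert traj.y[0] - traj.y[1] == pytest.approx(20.0)

    def test_round_trip_preserves_coordinates(self, tmp_path, zigzag):
        p = tmp_path / "zig.csv"
        hc.write_trajectory(zigzag, p)
        back = hc.read_trajectory(p)
        np.testing.assert_allclose(back.x, zigzag.x, atol=1e-6)
        np.testing.assert_allclose(back.y, zigzag.y, atol=1e-6)
        np.testing.assert_allclose(back.times, zigzag.times, atol=1e-6)

    def test_missing_columns_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b,c\n1,2,3\n2,3,4\n")
        with pytest.raises(TrajectoryFormatError):
            hc.read_trajectory(p)

    def test_duplicate_timestamp_is_validation_error(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("time_s,x_m,y_m\n0,0,0\n0,1,1\n")
        with pytest.raises(TrajectoryValidationError):
            hc.read_trajectory(p)

    def test_geographic_csv_is_projected(self, tmp_path):
        p = tmp_path / "geo.csv"
        p.write_text("time_s,lat,lon\n0,51.0,-1.0\n1,51.01,-1.0\n")
        traj = hc.read_trajectory(p)
        d = traj.path_length()
        assert 1105 <= d <= 1115


GPX = """<?xml version="1.0"?>
<gpx version="1.1" creator="test" xmlns="http://www.topografix.com/GPX/1/1">
 <trk><trkseg>
  <trkpt lat="51.0" lon="-1.0"><time>2017-05-01T10:00:00Z</time></trkpt>
  <trkpt lat="51.001" lon="-1.0"><time>2017-05-01T10:00:05Z</time></trkpt>
  <trkpt lat="51.002" lon="-1.0"><time>2017-05-01T10:00:10Z</time></trkpt>
 </trkseg></trk>
</gpx>
"""


class TestGpx:
    def test_gpx_track_parses_with_times_from_zero(self, tmp_path):
        p = tmp_path / "t.gpx"
        p.write_text(GPX)
        traj = hc.read_trajectory(p)
        assert traj.n_points == 3
        np.testing.assert_allclose(traj.times, [0.0, 5.0, 10.0])
        # two 0.001-degree latitude steps, ~111 m each
        assert traj.path_length() == pytest.approx(222.5, abs=2.0)


class TestProjection:
    def test_meridional_distance_matches_haversine(self):
        lat = np.array([51.0, 51.01])
        lon = np.array([-1.0, -1.0])
        x, y = hc.project_geographic(lat, lon, reference=(51.0, -1.0))
        d = math.hypot(x[1] - x[0], y[1] - y[0])
        oracle = haversine_m(51.0, -1.0, 51.01, -1.0)
        assert d == pytest.approx(oracle, rel=1e-3)
        assert 1105 <= d <= 1115

    @pytest.mark.parametrize("dlat,dlon", [(0.05, 0.0), (0.0, 0.08), (0.1, 0.1), (-0.05, 0.12)])
    def test_distances_match_ellipsoidal_oracle(self, dlat, dlon):
        lat1, lon1 = 51.3, -1.2
        lat2, lon2 = lat1 + dlat, lon1 + dlon
        x, y = hc.project_geographic(
            np.array([lat1, lat2]), np.array([lon1, lon2]), reference=(lat1, lon1)
        )
        d = math.hypot(x[1] - x[0], y[1] - y[0])
        oracle = local_ellipsoid_m(lat1, lon1, lat2, lon2)
        assert d == pytest.approx(oracle, rel=1e-3)

    def test_zone_from_longitude(self):
        assert utm_zone(-1.0) == 30
        assert utm_zone(3.0) == 31

    def test_points_far_outside_zone_rejected(self):
        with pytest.raises(ValueError):
            hc.project_geographic(
                np.array([51.0, 51.0]), np.array([-1.0, 14.0]), reference=(51.0, -1.0)
            )


class TestDownsample:
    def test_collinear_five_hz_to_one_hz(self):
        t = np.arange(11) * 0.2
        traj = hc.Trajectory(t, 2.0 * t, -1.0 * t)
        out = hc.downsample(traj, 1.0)
        np.testing.assert_allclose(out.times, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(out.x, [0.0, 2.0, 4.0], atol=1e-12)

    def test_constant_position_stays_constant(self):
        t = np.arange(11) * 0.2
        traj = hc.Trajectory(t, np.full(11, 3.0), np.full(11, 4.0))
        out = hc.downsample(traj, 1.0)
        assert np.all(out.x == 3.0) and np.all(out.y == 4.0)

    def test_idempotent_at_same_rate(self, straight_beeline):
        once = hc.downsample(straight_beeline, 1.0)
        twice = hc.downsample(once, 1.0)
        np.testing.assert_array_equal(once.times, twice.times)
        np.testing.assert_array_equal(once.x, twice.x)

    def test_path_length_never_increases(self):
        rng = np.random.default_rng(42)
        t = np.arange(51) * 0.2
        traj = hc.Trajectory(t, np.cumsum(rng.normal(0, 2, 51)), np.cumsum(rng.normal(0, 2, 51)))
        out = hc.downsample(traj, 1.0)
        assert out.path_length() <= traj.path_length() + 1e-9

    def test_endpoints_preserved_on_ragged_duration(self):
        t = np.arange(12) * 0.2  # 2.2 s: not a whole number of 1 s steps
        traj = hc.Trajectory(t, 3.0 * t, np.zeros(12))
        out = hc.downsample(traj, 1.0)
        assert out.times[-1] == pytest.approx(2.2)
        assert out.x[-1] == pytest.approx(traj.x[-1])

    def test_upsampling_is_rejected(self, straight_beeline):
        with pytest.raises(ValueError):
            hc.downsample(straight_beeline, 5.0)


class TestProximityFilter:
    def _line(self, offset):
        t = np.arange(10, dtype=float)
        return hc.Trajectory(t, np.full(10, offset), 10.0 * t)

    def test_identical_tracks_pass(self):
        a = self._line(0.0)
        assert hc.proximity_filter(a, a) is True

    def test_parallel_tracks_300m_apart_fail(self):
        assert hc.proximity_filter(self._line(0.0), self._line(300.0)) is False

    def test_peak_separation_just_under_threshold_passes(self):
        t = np.arange(11, dtype=float)
        a = hc.Trajectory(t, np.zeros(11), 10.0 * t)
        sep = 249.0 * np.sin(np.pi * t / t[-1])  # peaks at exactly 249 m mid-flight
        b = hc.Trajectory(t, sep, 10.0 * t)
        assert max(np.abs(sep)) <= 249.0
        assert hc.proximity_filter(a, b) is True

    def test_disjoint_time_support_is_error(self):
        t = np.arange(10, dtype=float)
        a = hc.Trajectory(t, np.zeros(10), t)
        b = hc.Trajectory(t + 100.0, np.zeros(10), t)
        with pytest.raises(ValueError):
            hc.proximity_filter(a, b)
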