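"""Track I/O, interpolation, centroid, local projection and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eggdrift.tracks import (
    DrifterTrack,
    EggSizeWindow,
    LocalFrame,
    centroid_track,
    classify_by_diameter,
    concentration_from_count,
    interpolate_position,
    read_drifter_track,
    read_observations,
    write_drifter_track,
    write_observations,
)


def _haversine_m(lat1, lon1, lat2, lon2, R=6371008.8):
    """Great-circle oracle for the equirectangular projection."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlmb = np.deg2rad(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * R * np.arcsin(np.sqrt(a))


def _track(times, lats, lons, **kw):
    return DrifterTrack("d1", np.asarray(times), np.asarray(lats), np.asarray(lons), **kw)


class TestReadDrifterTrack:
    def test_well_formed_identity(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time,lat,lon\n0,19.0,-80.0\n60,19.1,-80.1\n120,19.2,-80.2\n")
        trk = read_drifter_track(p)
        assert len(trk) == 3 and trk.n_rejected == 0
        np.testing.assert_allclose(trk.lats, [19.0, 19.1, 19.2])

    def test_malformed_row_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time,lat,lon\n0,19.0,-80.0\n60,oops,-80.1\n120,19.2,-80.2\n")
        trk = read_drifter_track(p)
        assert len(trk) == 2 and trk.n_rejected == 1

    def test_shuffled_rows_sorted_on_read(self, tmp_path):
        rows = [(t, 19 + t / 1e4, -80 - t / 1e4) for t in (300, 0, 240, 60, 120)]
        p = tmp_path / "t.csv"
        p.write_text("time,lat,lon\n" + "\n".join(f"{t},{la},{lo}" for t, la, lo in rows))
        trk = read_drifter_track(p)
        assert (np.diff(trk.times) > 0).all()
        srt = sorted(rows)
        np.testing.assert_allclose(trk.times, [r[0] for r in srt])
        np.testing.assert_allclose(trk.lats, [r[1] for r in srt])

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time,latitude,lon\n0,19,-80\n60,19,-80\n")
        with pytest.raises(ValueError, match="missing"):
            read_drifter_track(p)

    def test_too_few_rows_errors(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time,lat,lon\n0,19.0,-80.0\n")
        with pytest.raises(ValueError, match="fewer than 2"):
            read_drifter_track(p)

    def test_iso_timestamps(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "time,lat,lon\n2017-02-14T19:00:00,19.0,-80.0\n"
            "2017-02-14T20:00:00,19.1,-80.1\n"
        )
        trk = read_drifter_track(p)
        np.testing.assert_allclose(trk.times, [0.0, 3600.0])

    def test_roundtrip(self, tmp_path):
        trk = _track([0, 60, 120], [19.0, 19.1, 19.2], [-80.0, -80.1, -80.2])
        p = tmp_path / "t.csv"
        write_drifter_track(trk, p)
        back = read_drifter_track(p)
        np.testing.assert_allclose(back.lats, trk.lats)


class TestInterpolate:
    track = _track([0.0, 100.0, 200.0], [19.0, 19.2, 19.3], [-80.0, -80.2, -80.1])

    def test_exact_at_knot(self):
        p = interpolate_position(self.track, 100.0)
        assert (p.lat, p.lon) == (19.2, -80.2)

    def test_midpoint_mean(self):
        p = interpolate_position(self.track, 50.0)
        assert p.lat == pytest.approx(19.1) and p.lon == pytest.approx(-80.1)

    def test_refinement_consistency(self):
        # resample densely, rebuild a track, and re-interpolate: the
        # piecewise-linear function must be unchanged
        ts = np.linspace(0, 200, 401)
        pts = [interpolate_position(self.track, t) for t in ts]
        dense = _track(ts, [p.lat for p in pts], [p.lon for p in pts])
        for t in np.linspace(3.3, 196.7, 23):
            a = interpolate_position(self.track, t)
            b = interpolate_position(dense, t)
            assert abs(a.lat - b.lat) < 1e-9 and abs(a.lon - b.lon) < 1e-9

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError, match="outside"):
            interpolate_position(self.track, 201.0)


class TestCentroid:
    def test_single_track_resampled(self):
        trk = _track([0, 100, 200], [19.0, 19.2, 19.3], [-80.0, -80.2, -80.1])
        cen = centroid_track([trk], trk.times)
        np.testing.assert_allclose(cen.lats, trk.lats)
        np.testing.assert_allclose(cen.lons, trk.lons)

    def test_mirrored_tracks_constant_centroid(self):
        a = _track([0, 100], [19.0, 19.2], [-80.0, -80.4])
        b = _track([0, 100], [19.4, 19.2], [-80.4, -80.0])
        cen = centroid_track([a, b], [0.0, 50.0, 100.0])
        np.testing.assert_allclose(cen.lats, 19.2)
        np.testing.assert_allclose(cen.lons, -80.2)

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(5)
        tracks = [
            _track(
                np.linspace(0, 500, 11),
                19 + np.cumsum(rng.normal(0, 1e-3, 11)),
                -80 + np.cumsum(rng.normal(0, 1e-3, 11)),
            )
            for _ in range(5)
        ]
        times = np.linspace(10, 490, 7)
        cen = centroid_track(tracks, times)
        for i, t in enumerate(times):
            lats = [interpolate_position(trk, t).lat for trk in tracks]
            lons = [interpolate_position(trk, t).lon for trk in tracks]
            assert cen.lats[i] == pytest.approx(np.mean(lats), abs=1e-12)
            assert cen.lons[i] == pytest.approx(np.mean(lons), abs=1e-12)

    def test_inclusion_mask(self):
        a = _track([0, 100], [19.0, 19.0], [-80.0, -80.0])
        b = _track([0, 100], [20.0, 20.0], [-81.0, -81.0])
        mask = np.array([[True, True], [True, False]])
        cen = centroid_track([a, b], [0.0, 100.0], include=mask)
        assert cen.lats[0] == pytest.approx(19.5)
        assert cen.lats[1] == pytest.approx(19.0)  # b excluded at t=100

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            centroid_track([], [0.0])


class TestLocalFrame:
    frame = LocalFrame(19.65, -80.10)

    def test_origin_maps_to_zero(self):
        x, y = self.frame.to_local_xy(19.65, -80.10)
        assert x == 0.0 and y == 0.0

    def test_north_offset_matches_haversine(self):
        x, y = self.frame.to_local_xy(19.66, -80.10)
        assert x == pytest.approx(0.0, abs=1e-9)
        assert y == pytest.approx(1111.95, rel=1e-3)
        oracle = _haversine_m(19.65, -80.10, 19.66, -80.10)
        assert y == pytest.approx(oracle, rel=1e-3)

    def test_east_offset_matches_haversine(self):
        x, _ = self.frame.to_local_xy(19.65, -80.05)
        oracle = _haversine_m(19.65, -80.10, 19.65, -80.05)
        assert x == pytest.approx(oracle, rel=1e-3)

    @settings(derandomize=True, max_examples=100)
    @given(
        dlat=st.floats(-0.5, 0.5),
        dlon=st.floats(-0.5, 0.5),
    )
    def test_roundtrip_invertible(self, dlat, dlon):
        lat, lon = 19.65 + dlat, -80.10 + dlon
        x, y = self.frame.to_local_xy(lat, lon)
        lat2, lon2 = self.frame.to_geographic(x, y)
        assert abs(lat2 - lat) < 1e-9 and abs(lon2 - lon) < 1e-9


class TestClassification:
    def test_inside_window(self):
        assert classify_by_diameter(0.95)

    def test_above_window(self):
        assert not classify_by_diameter(1.30)

    def test_boundary_closed(self):
        assert classify_by_diameter(0.87) and classify_by_diameter(1.20)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            classify_by_diameter(0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        d=st.floats(0.01, 3.0),
        lo=st.floats(0.1, 1.0),
        widen=st.floats(0.0, 0.5),
    )
    def test_widening_never_declassifies(self, d, lo, widen):
        narrow = EggSizeWindow(lo, lo + 0.3)
        wide = EggSizeWindow(max(lo - widen, 1e-6), lo + 0.3 + widen)
        if classify_by_diameter(d, narrow):
            assert classify_by_diameter(d, wide)


class TestConcentration:
    @pytest.mark.parametrize(
        "count,volume,expected",
        [(264, 264.0, 1.0), (0, 264.0, 0.0), (10, 264.0, 10 / 264)],
    )
    def test_values(self, count, volume, expected):
        assert concentration_from_count(count, volume) == pytest.approx(expected)

    def test_bad_volume(self):
        with pytest.raises(ValueError):
            concentration_from_count(1, 0.0)


def test_observation_table_roundtrip(tmp_path, survey):
    p = tmp_path / "obs.csv"
    write_observations(survey.observations, p)
    back = read_observations(p)
    pd.testing.assert_frame_equal(back, survey.observations, check_dtype=False)
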