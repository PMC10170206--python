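"""Drifter tracks, tow observations and the centroid-relative local frame.

Drogued surface drifters released into the egg plume mark the advective
frame: subtracting the drifter-centroid position from every observation
removes advection, leaving diffusion and mortality to be modelled.  This
module reads and writes the timestamped position tables, interpolates and
averages tracks, converts geographic coordinates to a local metric frame
(x east, y north, z depth positive down), and applies the egg-diameter
classification window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeoPoint",
    "DrifterTrack",
    "LocalFrame",
    "EggSizeWindow",
    "TowObservation",
    "OBS_COLUMNS",
    "read_drifter_track",
    "write_drifter_track",
    "interpolate_position",
    "centroid_track",
    "classify_by_diameter",
    "concentration_from_count",
    "read_observations",
    "write_observations",
    "validate_observations",
]

logger = logging.getLogger(__name__)

#: Mean Earth radius in metres (IUGG).
EARTH_RADIUS_M = 6371008.8


class GeoPoint(NamedTuple):
    """A timestamped geographic position.

    time is in seconds since the release epoch (19.00 local time on the
    spawning night); lat/lon in decimal degrees.
    """

    time: float
    lat: float
    lon: float


@dataclass
class DrifterTrack:
    """Ordered sequence of drifter positions with strictly increasing times."""

    drifter_id: str
    times: np.ndarray  # seconds since release epoch
    lats: np.ndarray  # degrees N
    lons: np.ndarray  # degrees E
    n_rejected: int = 0  # malformed input rows dropped on read

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.times.size < 2:
            raise ValueError("a drifter track needs at least 2 points")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("track times must be strictly increasing")
        if not np.isfinite(self.times).all():
            raise ValueError("track times must be finite")
        if (np.abs(self.lats) > 90).any() or (np.abs(self.lons) > 180).any():
            raise ValueError("latitude/longitude out of range")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def points(self) -> list[GeoPoint]:
        return [GeoPoint(t, la, lo) for t, la, lo in zip(self.times, self.lats, self.lons)]

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) time in seconds."""
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class LocalFrame:
    """Equirectangular local tangent frame: x metres east, y metres north.

    Valid for the <=20 km scales of an egg-plume survey; the inverse is
    exact to well below 1e-9 degrees at these distances.
    """

    origin_lat: float
    origin_lon: float

    def to_local_xy(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        dlat = np.deg2rad(np.asarray(lat, dtype=float) - self.origin_lat)
        dlon = np.deg2rad(np.asarray(lon, dtype=float) - self.origin_lon)
        x = EARTH_RADIUS_M * np.cos(np.deg2rad(self.origin_lat)) * dlon
        y = EARTH_RADIUS_M * dlat
        return x, y

    def to_geographic(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        lat = self.origin_lat + np.rad2deg(np.asarray(y, dtype=float) / EARTH_RADIUS_M)
        lon = self.origin_lon + np.rad2deg(
            np.asarray(x, dtype=float)
            / (EARTH_RADIUS_M * np.cos(np.deg2rad(self.origin_lat)))
        )
        return lat, lon


@dataclass(frozen=True)
class EggSizeWindow:
    """Closed diameter interval (mm) classifying eggs as the target species."""

    d_min: float = 0.87
    d_max: float = 1.20

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ValueError("require 0 < d_min < d_max")


class TowObservation(NamedTuple):
    """One minute of towed-imaging sampling in the centroid-relative frame."""

    t: float  # hours since release
    x: float  # metres east of the drifter centroid
    y: float  # metres north of the drifter centroid
    z: float  # metres depth, positive down
    count: int  # eggs imaged in the minute
    volume: float = 264.0  # litres sampled in the minute


#: Canonical observation-table columns (delimited-text interface).
OBS_COLUMNS = ["t_hours", "x_m", "y_m", "z_m", "count", "volume_l"]


def read_drifter_track(
    path,
    drifter_id: str = "drifter",
    time_col: str = "time",
    lat_col: str = "lat",
    lon_col: str = "lon",
    epoch: pd.Timestamp | None = None,
    sep: str = ",",
) -> DrifterTrack:
    """Read a delimited drifter-position table.

    ``time`` may be ISO-8601 timestamps or numeric epoch/elapsed seconds.
    With ISO timestamps, ``epoch`` sets time zero (default: first valid
    timestamp).  Rows with unparseable fields are dropped and counted in
    ``DrifterTrack.n_rejected``; rows are sorted by time on read.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (time_col, lat_col, lon_col) if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    n_raw = len(df)

    t_num = pd.to_numeric(df[time_col], errors="coerce")
    if t_num.notna().sum() >= max(2, n_raw // 2):
        times = t_num
    else:
        stamps = pd.to_datetime(df[time_col], errors="coerce", utc=True, format="ISO8601")
        if epoch is None:
            epoch = stamps.dropna().min()
        times = (stamps - epoch).dt.total_seconds()
    lats = pd.to_numeric(df[lat_col], errors="coerce")
    lons = pd.to_numeric(df[lon_col], errors="coerce")

    ok = times.notna() & lats.notna() & lons.notna()
    ok &= lats.abs() <= 90
    ok &= lons.abs() <= 180
    n_rejected = int(n_raw - ok.sum())
    if n_rejected:
        logger.warning("read_drifter_track: rejected %d malformed row(s)", n_rejected)
    if ok.sum() < 2:
        raise ValueError(f"fewer than 2 valid rows in {path!r}")

    order = np.argsort(times[ok].to_numpy(), kind="stable")
    return DrifterTrack(
        drifter_id=drifter_id,
        times=times[ok].to_numpy()[order],
        lats=lats[ok].to_numpy()[order],
        lons=lons[ok].to_numpy()[order],
        n_rejected=n_rejected,
    )


def write_drifter_track(track: DrifterTrack, path, sep: str = ",") -> None:
    pd.DataFrame({"time": track.times, "lat": track.lats, "lon": track.lons}).to_csv(
        path, sep=sep, index=False
    )


def interpolate_position(track: DrifterTrack, t: float) -> GeoPoint:
    """Piecewise-linear position at time ``t`` seconds; exact at knots."""
    t0, t1 = track.span
    if not t0 <= t <= t1:
        raise ValueError(f"t={t} outside track span [{t0}, {t1}]; extrapolation refused")
    lat = float(np.interp(t, track.times, track.lats))
    lon = float(np.interp(t, track.times, track.lons))
    return GeoPoint(float(t), lat, lon)


def centroid_track(
    tracks: Sequence[DrifterTrack],
    times: np.ndarray,
    include: np.ndarray | None = None,
) -> DrifterTrack:
    """Per-time arithmetic-mean position of several drifter tracks.

    ``include`` is an optional boolean mask of shape (n_times, n_tracks)
    selecting which drifters contribute at each time (e.g. to drop drifters
    after they ground); every time must keep at least one drifter.  All
    requested times must lie within every included track's span.
    """
    if len(tracks) == 0:
        raise ValueError("empty track list")
    times = np.asarray(times, dtype=float)
    if include is None:
        include = np.ones((times.size, len(tracks)), dtype=bool)
    include = np.asarray(include, dtype=bool)
    if include.shape != (times.size, len(tracks)):
        raise ValueError("include mask must have shape (n_times, n_tracks)")
    if not include.any(axis=1).all():
        raise ValueError("every time must include at least one drifter")

    lat_mat = np.full((times.size, len(tracks)), np.nan)
    lon_mat = np.full((times.size, len(tracks)), np.nan)
    for j, trk in enumerate(tracks):
        for i, t in enumerate(times):
            if include[i, j]:
                p = interpolate_position(trk, t)
                lat_mat[i, j] = p.lat
                lon_mat[i, j] = p.lon
    with np.errstate(invalid="ignore"):
        lats = np.nanmean(np.where(include, lat_mat, np.nan), axis=1)
        lons = np.nanmean(np.where(include, lon_mat, np.nan), axis=1)
    return DrifterTrack("centroid", times, lats, lons)


def classify_by_diameter(d: float, window: EggSizeWindow = EggSizeWindow()) -> bool:
    """True iff diameter ``d`` (mm) lies in the closed window [d_min, d_max]."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    return window.d_min <= d <= window.d_max


def concentration_from_count(count, volume=264.0):
    """Convert an egg count per minute to eggs per litre.

    ``volume`` is the litres sampled during the minute (imaging-volume
    throughput; default 264 l min^-1).
    """
    count = np.asarray(count, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if (volume <= 0).any():
        raise ValueError("sampled volume must be positive")
    if (count < 0).any():
        raise ValueError("count must be non-negative")
    out = count / volume
    return float(out) if out.ndim == 0 else out


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Check an observation table against the canonical schema.

    Requires OBS_COLUMNS, non-negative integer counts, positive volumes and
    non-negative depths.  Returns the frame with canonical dtypes.
    """
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    df = df[OBS_COLUMNS].copy()
    counts = df["count"].to_numpy()
    if not np.allclose(counts, np.round(counts)) or (counts < 0).any():
        raise ValueError("counts must be non-negative integers")
    df["count"] = np.round(counts).astype(int)
    if (df["volume_l"].to_numpy() <= 0).any():
        raise ValueError("volumes must be positive")
    if (df["z_m"].to_numpy() < 0).any():
        raise ValueError("depths must be non-negative (positive-down)")
    for c in ("t_hours", "x_m", "y_m", "z_m", "volume_l"):
        df[c] = df[c].astype(float)
    return df


def read_observations(path, sep: str = ",") -> pd.DataFrame:
    """Read a per-minute tow observation table (see OBS_COLUMNS)."""
    return validate_observations(pd.read_csv(path, sep=sep))


def write_observations(df: pd.DataFrame, path, sep: str = ",") -> None:
    validate_observations(df).to_csv(path, sep=sep, index=False)
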