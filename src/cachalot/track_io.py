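"""Reading, cleaning and summarising Argos location tables.

The core data model is a :class:`Track`: one animal's time-ordered Argos
fixes, each carrying a location class from {3, 2, 1, 0, A, B, Z}. Class Z
marks a failed localization and is dropped during cleaning; tied timestamps
(several fixes resolved to the same second) are nudged forward by 1 s until
the sequence is strictly increasing. All timestamps are GMT; no timezone
inference is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

LOC_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")


class EmptyTrackError(ValueError):
    """Raised when a track has no usable locations after cleaning."""


class UndefinedMetricsError(ValueError):
    """Raised when summary metrics are requested for a track with <2 fixes."""


@dataclass(frozen=True)
class RawLocation:
    animal_id: str
    timestamp: pd.Timestamp  # GMT
    lat: float
    lon: float
    loc_class: str

    def __post_init__(self):
        if self.loc_class not in LOC_CLASSES:
            raise ValueError(f"invalid location class {self.loc_class!r}")
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({self.lat}, {self.lon})")


@dataclass
class Track:
    """One animal's time-ordered Argos fixes plus tagging metadata."""

    animal_id: str
    locations: list[RawLocation]
    tagging_location: tuple[float, float] | None = None  # (lat, lon)
    tagging_date: date | None = None

    def __post_init__(self):
        self.locations = sorted(self.locations, key=lambda r: r.timestamp)
        if self.tagging_location is None and self.locations:
            first = self.locations[0]
            self.tagging_location = (first.lat, first.lon)
        if self.tagging_date is None and self.locations:
            self.tagging_date = self.locations[0].timestamp.date()

    def __len__(self) -> int:
        return len(self.locations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.animal_id for r in self.locations],
                "timestamp": [r.timestamp for r in self.locations],
                "lat": [r.lat for r in self.locations],
                "lon": [r.lon for r in self.locations],
                "lc": [r.loc_class for r in self.locations],
            }
        )


@dataclass(frozen=True)
class TrackMeta:
    track_duration_d: float
    n_days_with_locations: int
    n_locations: int
    mean_time_step_h: float
    max_gap_d: float
    n_gaps_gt_threshold: int


@dataclass(frozen=True)
class Dialect:
    """Column layout of an input location table.

    Defaults match the Wildlife Computers "-Locations.csv" layout
    (DeployID / Date / Latitude / Longitude / Quality, comma-separated).
    """

    id_col: str = "DeployID"
    time_col: str = "Date"
    lat_col: str = "Latitude"
    lon_col: str = "Longitude"
    class_col: str = "Quality"
    delimiter: str = ","
    datetime_format: str | None = None  # None -> flexible ISO-ish parsing

    @property
    def required(self) -> tuple[str, ...]:
        return (self.id_col, self.time_col, self.lat_col, self.lon_col, self.class_col)


CANONICAL_DIALECT = Dialect(
    id_col="id", time_col="timestamp", lat_col="lat", lon_col="lon", class_col="lc"
)


def read_locations(path, dialect: Dialect = Dialect()) -> list[Track]:
    """Read a delimited location table into one Track per animal.

    Unparseable rows (bad coordinates, bad timestamps, unknown classes) are
    reported through a warning that lists their row numbers; they are never
    silently dropped without notice. A missing required column is a hard
    error naming the column.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    for col in dialect.required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if df.empty:
        warnings.warn(f"empty location table: {path}", stacklevel=2)
        return []

    ts = pd.to_datetime(
        df[dialect.time_col], format=dialect.datetime_format, errors="coerce", utc=True
    ).dt.tz_localize(None)
    lat = pd.to_numeric(df[dialect.lat_col], errors="coerce")
    lon = pd.to_numeric(df[dialect.lon_col], errors="coerce")
    lc = df[dialect.class_col].astype(str).str.strip().str.upper()

    ok = (
        ts.notna()
        & lat.between(-90, 90)
        & lon.between(-180, 180)
        & lc.isin(LOC_CLASSES)
    )
    bad = df.index[~ok]
    if len(bad):
        warnings.warn(
            f"{len(bad)} unparseable location row(s) skipped "
            f"(file rows {[int(i) + 2 for i in bad[:20]]}{'...' if len(bad) > 20 else ''})",
            stacklevel=2,
        )

    tracks: list[Track] = []
    sub = df.loc[ok]
    for animal_id, grp in sub.groupby(df.loc[ok, dialect.id_col], sort=False):
        locs = [
            RawLocation(str(animal_id), ts[i], float(lat[i]), float(lon[i]), lc[i])
            for i in grp.index
        ]
        tracks.append(Track(str(animal_id), locs))
    return tracks


def write_locations(tracks: Iterable[Track], path) -> None:
    """Write tracks to the canonical CSV layout (id, ISO-8601 GMT, lat, lon, lc)."""
    frames = [t.to_frame() for t in tracks]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["id", "timestamp", "lat", "lon", "lc"]
    )
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def track_to_geojson(t: Track) -> dict:
    return {
        "type": "Feature",
        "properties": {"id": t.animal_id},
        "geometry": {
            "type": "LineString",
            "coordinates": [[r.lon, r.lat] for r in t.locations],
        },
    }


def clean_track(t: Track) -> Track:
    """Remove class-Z fixes and enforce strictly increasing timestamps.

    Z-class fixes (failed localizations) are removed first; then any fix
    whose timestamp does not exceed its predecessor's is shifted forward by
    1 s, repeatedly, until the whole sequence is strictly increasing.
    """
    kept = [r for r in t.locations if r.loc_class != "Z"]
    if not kept:
        raise EmptyTrackError(f"track {t.animal_id} empty after class-Z removal")
    out: list[RawLocation] = [kept[0]]
    for r in kept[1:]:
        if r.timestamp <= out[-1].timestamp:
            r = replace(r, timestamp=out[-1].timestamp + pd.Timedelta(seconds=1))
        out.append(r)
    return Track(t.animal_id, out, t.tagging_location, t.tagging_date)


def track_meta(t: Track, gap_threshold_h: float = 72.0) -> TrackMeta:
    """Per-track tag-performance summary (duration, coverage, gaps)."""
    if len(t) < 2:
        raise UndefinedMetricsError(
            f"track {t.animal_id}: need >=2 locations for summary metrics"
        )
    times = pd.Series([r.timestamp for r in t.locations])
    span_h = (times.iloc[-1] - times.iloc[0]).total_seconds() / 3600.0
    gaps_h = times.diff().dropna().dt.total_seconds() / 3600.0
    return TrackMeta(
        track_duration_d=span_h / 24.0,
        n_days_with_locations=int(times.dt.date.nunique()),
        n_locations=len(t),
        mean_time_step_h=span_h / (len(t) - 1),
        max_gap_d=float(gaps_h.max()) / 24.0,
        n_gaps_gt_threshold=int((gaps_h > gap_threshold_h).sum()),
    )
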