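"""Migration phenology: classifying migrants and dating the legs of the
breeding cycle.

The annual cycle of an adult male sperm whale tagged on the Arctic foraging
grounds is segmented into four phases using only the geometry and kinematics
of the track:

1. *Migrant classification*: an animal whose maximum great-circle
   displacement from its tagging location reaches 1,000 km is a migrant
   (the distribution of maxima is strongly bimodal around that value).
2. *Foraging polygon*: the 100% minimum convex polygon (MCP) over the
   non-migrants' locations, subsampled to one fix every other day to reduce
   autocorrelation. This polygon delimits the northern foraging grounds.
3. *Departure (start of the N-S transit)*: the last exit from the foraging
   polygon that is not followed by a re-entry — unless that re-entry is the
   eventual return from the southern breeding grounds.
4. *Arrival at the breeding area*: the first 2-h position south of 45 degN
   (the classical delineation of North Atlantic breeding latitudes) at
   which the animal is decelerating, i.e. where the first derivative of the
   loess-smoothed speed series (span 0.2, local quadratic) is negative.
5. *Departure from the breeding area*: the first post-arrival position
   north of the average arrival latitude (cohort mean by default).
6. *Return north (end of the S-N transit)*: the first re-entry into the
   foraging polygon after leaving the breeding area.

Durations are whole-day differences of the event dates (GMT), so the three
leg durations add up exactly to the whole-cycle duration whenever all four
dates exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon

from ._geo import LocalProjection, haversine_km
from .metrics import step_metrics
from .ssm import RegularizedTrack
from .track_io import Track

MIGRANT_THRESHOLD_KM = 1000.0
BREEDING_LAT_LIMIT = 45.0
LOESS_SPAN = 0.2


class DegenerateGeometryError(ValueError):
    """Hull construction failed (collinear or too few points)."""


# ---------------------------------------------------------------------------
# migrant classification


def classify_migrant(t: Track, threshold_km: float = MIGRANT_THRESHOLD_KM) -> tuple[bool, float]:
    """Migrant flag and maximum great-circle displacement from tagging.

    The threshold is inclusive: an animal reaching exactly ``threshold_km``
    counts as a migrant.
    """
    lat0, lon0 = t.tagging_location
    lat = np.array([r.lat for r in t.locations])
    lon = np.array([r.lon for r in t.locations])
    if len(lat) == 0:
        return False, 0.0
    dmax = float(haversine_km(lat0, lon0, lat, lon).max())
    return dmax >= threshold_km, dmax


# ---------------------------------------------------------------------------
# foraging polygon (100% MCP)


@dataclass
class ForagingPolygon:
    """100% minimum convex polygon in an equal-area plane.

    ``vertices_lonlat`` closes the ring; containment tests are closed (a
    point on the boundary is inside).
    """

    polygon: Polygon  # in projected km
    projection: LocalProjection
    area_km2: float
    vertices_lonlat: list[tuple[float, float]]

    def contains(self, lat, lon) -> np.ndarray:
        x, y = self.projection.forward(lat, lon)
        x, y = np.atleast_1d(x), np.atleast_1d(y)
        # shapely covers() is closed: boundary points count as inside
        return np.array([self.polygon.covers(Point(xi, yi)) for xi, yi in zip(x, y)])


def _mcp_from_points(lat: np.ndarray, lon: np.ndarray, projection: LocalProjection | None = None) -> ForagingPolygon:
    if len(lat) < 3:
        raise DegenerateGeometryError("need at least 3 points for an MCP")
    proj = projection or LocalProjection(float(np.mean(lat)), float(np.mean(lon)), kind="laea")
    x, y = proj.forward(lat, lon)
    hull = MultiPoint(list(zip(x, y))).convex_hull
    if hull.geom_type != "Polygon" or hull.area < 1e-6:
        raise DegenerateGeometryError("points are (near-)collinear; MCP is degenerate")
    vx, vy = hull.exterior.coords.xy
    vlat, vlon = proj.inverse(np.array(vx), np.array(vy))
    return ForagingPolygon(
        polygon=hull,
        projection=proj,
        area_km2=float(hull.area),
        vertices_lonlat=[(float(lo), float(la)) for la, lo in zip(vlat, vlon)],
    )


def foraging_polygon(non_migrants: Sequence[Track], subsample_every_d: float = 2.0) -> ForagingPolygon:
    """100% MCP over non-migrant locations thinned to one fix per 2 days."""
    lats, lons = [], []
    for t in non_migrants:
        if not t.locations:
            continue
        t0 = t.locations[0].timestamp
        last_bin = -1
        for r in t.locations:
            b = int((r.timestamp - t0).total_seconds() // (subsample_every_d * 86400))
            if b != last_bin:
                lats.append(r.lat)
                lons.append(r.lon)
                last_bin = b
    return _mcp_from_points(np.array(lats), np.array(lons))


def mcp_area_km2(lat: np.ndarray, lon: np.ndarray) -> float:
    """Area of the 100% MCP over arbitrary positions (equal-area plane)."""
    return _mcp_from_points(np.asarray(lat), np.asarray(lon)).area_km2


# ---------------------------------------------------------------------------
# loess-smoothed speed and its derivative


@dataclass
class SmoothedSpeedCurve:
    timestamp: np.ndarray
    lat: np.ndarray
    speed_kmh: np.ndarray
    smoothed: np.ndarray
    derivative: np.ndarray  # d(smoothed speed)/d(step), central differences


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = LOESS_SPAN, degree: int = 2) -> np.ndarray:
    """Tricube-weighted local polynomial regression evaluated at each x.

    Matches the classical loess definition: for each target point the
    nearest ``ceil(span * n)`` observations get tricube weights scaled by
    the span radius, and a weighted degree-``degree`` polynomial is fitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n == 0:
        return np.empty(0)
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for j, x0 in enumerate(xs):
        dist = np.abs(xs - x0)
        idx = np.argpartition(dist, q - 1)[:q]
        h = dist[idx].max()
        if h <= 0:
            out[j] = ys[idx].mean()
            continue
        w = (1.0 - (dist[idx] / h) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        dx = xs[idx] - x0
        A = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], ys[idx] * sw, rcond=None)
        out[j] = coef[0]
    res = np.empty(n)
    res[order] = out
    return res


def smoothed_speed_curve(rt: RegularizedTrack, span: float = LOESS_SPAN) -> SmoothedSpeedCurve:
    """Loess-smoothed 2-h speed series (segments only) with its derivative."""
    sm = step_metrics(rt)
    ok = sm["speed_kmh"].notna().values
    ts = sm["timestamp"].values[ok]
    lat = rt.data["lat"].values[ok]
    sp = sm["speed_kmh"].values[ok]
    if len(sp) < 5:
        return SmoothedSpeedCurve(ts, lat, sp, np.full(len(sp), np.nan), np.full(len(sp), np.nan))
    th = ts.astype("datetime64[s]").astype(float) / 3600.0
    smooth = loess_smooth(th, sp, span=span)
    deriv = np.gradient(smooth, th)
    return SmoothedSpeedCurve(ts, lat, sp, smooth, deriv)


# ---------------------------------------------------------------------------
# event detectors


def _inside_series(rt: RegularizedTrack, poly: ForagingPolygon) -> np.ndarray:
    return poly.contains(rt.data["lat"].values, rt.data["lon"].values)


def departure_from_positions(lat: np.ndarray, lon: np.ndarray, ts: np.ndarray,
                             poly: ForagingPolygon,
                             breeding_lat: float = BREEDING_LAT_LIMIT) -> date | None:
    """Definitive polygon-exit date for an arbitrary position series."""
    inside = poly.contains(lat, lon)
    n = len(inside)
    if n == 0 or not inside.any():
        return None
    exits = [i for i in range(1, n) if inside[i - 1] and not inside[i]]
    for i in exits:
        later_in = np.nonzero(inside[i:])[0]
        if len(later_in) == 0:
            return pd.Timestamp(ts[i]).date()
        j = i + later_in[0]
        if np.nanmin(lat[i:j]) < breeding_lat:
            # the next re-entry is the return from the breeding grounds
            return pd.Timestamp(ts[i]).date()
    return None


def detect_departure(rt: RegularizedTrack, poly: ForagingPolygon,
                     breeding_lat: float = BREEDING_LAT_LIMIT) -> date | None:
    """Date of the definitive exit from the foraging polygon.

    The qualifying exit is the last one not followed by a re-entry — except
    that a re-entry occurring after the animal has been south of
    ``breeding_lat`` is the S-N return and does not disqualify the exit.
    Returns None when the animal never leaves the polygon.
    """
    return departure_from_positions(
        rt.data["lat"].values, rt.data["lon"].values, rt.data["timestamp"].values,
        poly, breeding_lat,
    )


def detect_arrival(
    rt_segments: RegularizedTrack,
    departure: date,
    curve: SmoothedSpeedCurve | None = None,
    lat_limit: float = BREEDING_LAT_LIMIT,
    span: float = LOESS_SPAN,
) -> date | None:
    """First post-departure 2-h position south of ``lat_limit`` where the
    loess-smoothed speed has a negative first derivative."""
    if curve is None:
        curve = smoothed_speed_curve(rt_segments, span=span)
    if len(curve.timestamp) == 0:
        return None
    after = curve.timestamp >= np.datetime64(pd.Timestamp(departure))
    cand = after & (curve.lat < lat_limit) & (curve.derivative < 0)
    idx = np.nonzero(cand)[0]
    if len(idx) == 0:
        return None
    return pd.Timestamp(curve.timestamp[idx[0]]).date()


def detect_breeding_departure(
    rt: RegularizedTrack,
    arrival: date,
    arrival_lats: Sequence[float],
) -> date | None:
    """First post-arrival position north of the mean arrival latitude.

    ``arrival_lats`` is the cohort's arrival latitudes (per the pooled
    definition of the breeding-area boundary); pass a single element for the
    per-individual variant.
    """
    if len(arrival_lats) == 0:
        return None
    mean_lat = float(np.mean(arrival_lats))
    ts = rt.data["timestamp"].values
    lat = rt.data["lat"].values
    after = ts > np.datetime64(pd.Timestamp(arrival)) + np.timedelta64(1, "D")
    cand = after & (lat > mean_lat)
    idx = np.nonzero(cand)[0]
    if len(idx) == 0:
        return None
    return pd.Timestamp(ts[idx[0]]).date()


def detect_return_north(rt: RegularizedTrack, poly: ForagingPolygon, breeding_departure: date) -> date | None:
    """First re-entry into the foraging polygon after leaving the breeding area."""
    inside = _inside_series(rt, poly)
    ts = rt.data["timestamp"].values
    after = ts >= np.datetime64(pd.Timestamp(breeding_departure))
    idx = np.nonzero(after & inside)[0]
    if len(idx) == 0:
        return None
    return pd.Timestamp(ts[idx[0]]).date()


def arrival_latitude(rt: RegularizedTrack, arrival: date) -> float | None:
    """Latitude of the first position on the arrival date."""
    ts = rt.data["timestamp"].values
    idx = np.nonzero(ts >= np.datetime64(pd.Timestamp(arrival)))[0]
    if len(idx) == 0:
        return None
    return float(rt.data["lat"].values[idx[0]])


# ---------------------------------------------------------------------------
# summaries


@dataclass
class PhenologyRecord:
    """Machine twin of one row of the migration-summary table."""

    animal_id: str
    is_migrant: bool
    max_distance_from_tagging_km: float
    start_migration_date: date | None = None
    arrival_breeding_date: date | None = None
    departure_breeding_date: date | None = None
    return_north_date: date | None = None
    duration_ns_d: int | None = None
    duration_breeding_d: int | None = None
    duration_sn_d: int | None = None
    duration_cycle_d: int | None = None
    cumdist_ns_km: float | None = None
    cumdist_breeding_km: float | None = None
    cumdist_sn_km: float | None = None
    cumdist_cycle_km: float | None = None
    breeding_mcp_km2: float | None = None


def durations_from_dates(
    start: date | None,
    arrival: date | None,
    breeding_departure: date | None,
    return_north: date | None,
) -> tuple[int | None, int | None, int | None, int | None]:
    """Whole-day leg durations (N-S, breeding, S-N, whole cycle).

    Raises on out-of-order dates; a zero-length leg is allowed but flagged
    upstream as suspicious.
    """
    pairs = [(start, arrival), (arrival, breeding_departure), (breeding_departure, return_north)]
    out = []
    for a, b in pairs:
        if a is not None and b is not None:
            d = (b - a).days
            if d < 0:
                raise ValueError(f"event dates out of order: {a} > {b}")
            out.append(d)
        else:
            out.append(None)
    cycle = (return_north - start).days if (start is not None and return_north is not None) else None
    return out[0], out[1], out[2], cycle


def _cumdist_between(rt: RegularizedTrack, a: date | None, b: date | None) -> float | None:
    if a is None or b is None:
        return None
    sm = step_metrics(rt)
    ts = sm["timestamp"].values
    cd = sm["cumulative_distance_km"].values
    ia = np.searchsorted(ts, np.datetime64(pd.Timestamp(a)))
    ib = np.searchsorted(ts, np.datetime64(pd.Timestamp(b)))
    ia, ib = min(ia, len(cd) - 1), min(ib, len(cd) - 1)
    return float(cd[ib] - cd[ia])


def summarize_phenology(
    t: Track,
    rt_whole: RegularizedTrack,
    is_migrant: bool,
    max_dist_km: float,
    start: date | None,
    arrival: date | None,
    breeding_departure: date | None,
    return_north: date | None,
) -> PhenologyRecord:
    """Assemble one animal's phenology record from resolved event dates."""
    for name, a, b in (
        ("arrival before departure", start, arrival),
        ("breeding departure before arrival", arrival, breeding_departure),
        ("return before breeding departure", breeding_departure, return_north),
    ):
        if a is not None and b is not None and b < a:
            raise ValueError(f"animal {t.animal_id}: {name}")
    d_ns, d_b, d_sn, d_cycle = durations_from_dates(start, arrival, breeding_departure, return_north)
    rec = PhenologyRecord(
        animal_id=t.animal_id,
        is_migrant=is_migrant,
        max_distance_from_tagging_km=max_dist_km,
        start_migration_date=start,
        arrival_breeding_date=arrival,
        departure_breeding_date=breeding_departure,
        return_north_date=return_north,
        duration_ns_d=d_ns,
        duration_breeding_d=d_b,
        duration_sn_d=d_sn,
        duration_cycle_d=d_cycle,
        cumdist_ns_km=_cumdist_between(rt_whole, start, arrival),
        cumdist_breeding_km=_cumdist_between(rt_whole, arrival, breeding_departure),
        cumdist_sn_km=_cumdist_between(rt_whole, breeding_departure, return_north),
        cumdist_cycle_km=_cumdist_between(rt_whole, start, return_north),
    )
    if arrival is not None:
        ts = rt_whole.data["timestamp"].values
        lo = ts >= np.datetime64(pd.Timestamp(arrival))
        hi = (
            ts < np.datetime64(pd.Timestamp(breeding_departure))
            if breeding_departure is not None
            else np.ones(len(ts), dtype=bool)
        )
        sel = lo & hi
        if sel.sum() >= 3:
            try:
                rec.breeding_mcp_km2 = mcp_area_km2(
                    rt_whole.data["lat"].values[sel], rt_whole.data["lon"].values[sel]
                )
            except DegenerateGeometryError:
                rec.breeding_mcp_km2 = None
    return rec


def cohort_summary(records: Sequence[PhenologyRecord]) -> dict:
    """Cohort mean +- SD (sample SD, n-1), rounded to whole days."""

    def stats(vals):
        vals = [v for v in vals if v is not None]
        if not vals:
            return {"n": 0}
        out = {"n": len(vals), "mean": int(round(float(np.mean(vals)))),
               "min": int(min(vals)), "max": int(max(vals))}
        out["sd"] = int(round(float(np.std(vals, ddof=1)))) if len(vals) > 1 else None
        return out

    migrants = [r for r in records if r.is_migrant]
    starts = [r.start_migration_date for r in migrants if r.start_migration_date]
    # departures are asynchronous across years, so the interesting span is
    # within the calendar year (day-of-year), not between absolute dates
    doys = [d.timetuple().tm_yday for d in starts]
    span_d = (max(doys) - min(doys)) if len(doys) >= 2 else None
    return {
        "n_animals": len(records),
        "n_migrants": len(migrants),
        "duration_ns_d": stats([r.duration_ns_d for r in migrants]),
        "duration_breeding_d": stats([r.duration_breeding_d for r in migrants]),
        "duration_sn_d": stats([r.duration_sn_d for r in migrants]),
        "duration_cycle_d": stats([r.duration_cycle_d for r in migrants]),
        "departure_span_d": span_d,
    }


def records_to_frame(records: Sequence[PhenologyRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
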