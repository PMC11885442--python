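from datetime import date

import numpy as np
import pandas as pd
import pytest

from cachalot import (
    classify_migrant,
    detect_arrival,
    detect_breeding_departure,
    detect_departure,
    detect_return_north,
    durations_from_dates,
    foraging_polygon,
    loess_smooth,
    mcp_area_km2,
    smoothed_speed_curve,
)
from cachalot._geo import LocalProjection
from cachalot.phenology import DegenerateGeometryError, _mcp_from_points

from conftest import make_regularized, make_track

PROJ = LocalProjection(70.0, 15.0, "aeqd")


def _track_at_distances(dists_km, bearing_deg=180.0):
    """Track starting at the projection centre, visiting given ranges."""
    th = np.arange(len(dists_km)) * 2.0
    ang = np.radians(bearing_deg)
    xs = np.array(dists_km) * np.sin(ang)
    ys = np.array(dists_km) * np.cos(ang)
    lats, lons = PROJ.inverse(xs, ys)
    return make_track(th, lats, lons)


# ---------------------------------------------------------------------------
# migrant classification


@pytest.mark.parametrize(
    "max_km,expected",
    [(0.0, False), (999.0, False), (1000.0, True), (1001.0, True), (1010.0, True)],
)
def test_migrant_threshold_boundary(max_km, expected):
    t = _track_at_distances([0.0, max_km / 2, max_km])
    flag, dmax = classify_migrant(t)
    assert flag is expected
    assert dmax == pytest.approx(max_km, rel=0.001)


# ---------------------------------------------------------------------------
# minimum convex polygon


def test_square_hull_area():
    """Four points on a 100 x 100 km square give a 10,000 km^2 MCP."""
    xy = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
    lat, lon = LocalProjection(70, 15, "laea").inverse(xy[:, 0], xy[:, 1])
    assert mcp_area_km2(lat, lon) == pytest.approx(10000.0, rel=0.01)


def _exhaustive_hull_vertices(pts):
    """O(n^3) hull: an edge (i, j) is on the hull iff every other point lies
    on one side; hull vertices are the endpoints of such edges."""
    n = len(pts)
    verts = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            others = np.delete(cross, [i, j])
            if np.all(others > 1e-12) or np.all(others < -1e-12):
                verts.add(i)
                verts.add(j)
    return verts


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_hull_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 13)
    pts = rng.uniform(-200, 200, (n, 2))
    proj = LocalProjection(70, 15, "laea")
    poly = _mcp_from_points(*proj.inverse(pts[:, 0], pts[:, 1]), projection=proj)
    hull_xy = np.array(poly.polygon.exterior.coords)[:-1]
    expected = _exhaustive_hull_vertices(pts)
    got = set()
    for v in hull_xy:
        d = np.linalg.norm(pts - v, axis=1)
        got.add(int(np.argmin(d)))
        assert d.min() < 1e-6
    assert got == expected


def test_collinear_points_degenerate():
    lat, lon = PROJ.inverse(np.array([0.0, 10.0, 20.0]), np.array([0.0, 0.0, 0.0]))
    with pytest.raises(DegenerateGeometryError):
        _mcp_from_points(lat, lon)


def test_foraging_polygon_subsamples_and_contains_inputs():
    rng = np.random.default_rng(8)
    tracks = []
    for k in range(3):
        th = np.arange(0, 24 * 30, 3.0)  # 30 d at 3-h steps
        xy = rng.normal(0, 40, (len(th), 2)) + rng.uniform(-50, 50, 2)
        lats, lons = PROJ.inverse(xy[:, 0], xy[:, 1])
        tracks.append(make_track(th, lats, lons, animal_id=f"nm{k}"))
    poly = foraging_polygon(tracks, subsample_every_d=2.0)
    # 100% contour: every subsampled point is covered (closed polygon)
    for t in tracks:
        t0 = t.locations[0].timestamp
        seen = set()
        sub = []
        for r in t.locations:
            b = int((r.timestamp - t0).total_seconds() // (2 * 86400))
            if b not in seen:
                seen.add(b)
                sub.append(r)
        inside = poly.contains([r.lat for r in sub], [r.lon for r in sub])
        assert inside.all()
    assert poly.area_km2 > 0


# ---------------------------------------------------------------------------
# loess


def test_loess_reproduces_polynomial():
    """A degree-2 local fit is exact (to numerics) on a global quadratic."""
    x = np.linspace(0, 10, 80)
    y = 2.0 + 0.5 * x - 0.3 * x**2
    sm = loess_smooth(x, y, span=0.3, degree=2)
    assert np.allclose(sm, y, atol=1e-8)


def test_loess_smooths_noise_and_derivative_sign():
    rng = np.random.default_rng(0)
    x = np.linspace(0, 4 * np.pi, 400)
    y = np.sin(x) + rng.normal(0, 0.1, 400)
    sm = loess_smooth(x, y, span=0.2)
    assert np.sqrt(np.mean((sm - np.sin(x)) ** 2)) < 0.08
    d = np.gradient(sm, x)
    # decreasing on (pi/2, 3 pi/2) sufficiently inside the interval
    sel = (x > 0.6 * np.pi) & (x < 1.4 * np.pi)
    assert np.all(d[sel] < 0)


# ---------------------------------------------------------------------------
# event detectors on constructed planar tracks


def _poly_square(half_km=100.0):
    xy = np.array(
        [[-half_km, -half_km], [half_km, -half_km], [half_km, half_km], [-half_km, half_km]]
    )
    lat, lon = PROJ.inverse(xy[:, 0], xy[:, 1])
    return _mcp_from_points(lat, lon, projection=LocalProjection(70, 15, "laea"))


def _southbound_rt(exit_day, brief_excursion_day=None, n_days=80, south_kmd=110.0):
    """Inside the square until exit_day, then heading away south for good."""
    steps = int(n_days * 12)
    xy = np.zeros((steps, 2))
    day = np.arange(steps) / 12.0
    out = day >= exit_day
    xy[out, 1] = -(day[out] - exit_day) * south_kmd - 1.0
    if brief_excursion_day is not None:
        exc = (day >= brief_excursion_day) & (day < brief_excursion_day + 1.0)
        xy[exc, 1] = -150.0
    return make_regularized(xy, center=(70.0, 15.0))


def test_departure_simple_exit():
    rt = _southbound_rt(exit_day=40)
    poly = _poly_square()
    dep = detect_departure(rt, poly)
    assert dep == date(2022, 1, 1) + pd.Timedelta(days=40)


def test_departure_ignores_brief_excursion():
    rt = _southbound_rt(exit_day=60, brief_excursion_day=20)
    dep = detect_departure(rt, _poly_square())
    assert dep == date(2022, 1, 1) + pd.Timedelta(days=60)


def test_departure_none_for_resident():
    xy = np.tile([10.0, -10.0], (600, 1))
    rt = make_regularized(xy)
    assert detect_departure(rt, _poly_square()) is None


def _decelerating_arrival_case(cross_day=35.0, slow_start_day=33.0, n_days=60):
    """Southbound transit that begins slowing before it crosses 45 degN."""
    steps = int(n_days * 12)
    t_day = np.arange(steps) / 12.0
    # gradual deceleration from 110 to 40 km/d over ten days
    speed = np.clip(110.0 - 7.0 * np.clip(t_day - slow_start_day, 0.0, 10.0), 40.0, None)
    # choose start latitude so 45 degN is crossed near cross_day; a
    # cross_day beyond the track keeps the whole track north of 45
    if cross_day >= n_days:
        dist_to_45 = np.sum(speed) / 12.0 + 100.0
    else:
        dist_to_45 = np.sum(speed[: int(cross_day * 12)]) / 12.0
    start_lat = 45.0 + dist_to_45 / 111.19
    y = -np.cumsum(speed) / 12.0
    lat = start_lat + y / 111.19
    lon = np.full(steps, 0.0)
    proj = LocalProjection(60.0, 0.0, "aeqd")
    x_km, y_km = proj.forward(lat, lon)
    df = pd.DataFrame(
        {
            "timestamp": pd.date_range("2022-01-01", periods=steps, freq="2h"),
            "lat": lat,
            "lon": lon,
            "x_km": x_km,
            "y_km": y_km,
            "sd_x_km": 0.1,
            "sd_y_km": 0.1,
            "segment_id": 0,
        }
    )
    from cachalot.ssm import RegularizedTrack

    return RegularizedTrack("arr", df, "segments_only", proj)


def test_arrival_at_deceleration_south_of_45():
    rt = _decelerating_arrival_case()
    arr = detect_arrival(rt, departure=date(2022, 1, 1))
    assert arr is not None
    # truth: the first sub-45 position (the animal is already slowing there)
    cross_idx = int(np.argmax(rt.data["lat"].values < 45.0))
    truth = rt.data["timestamp"].iloc[cross_idx].date()
    assert abs((arr - truth).days) <= 2


def test_arrival_latitude_gate():
    # track never south of 45: no arrival even while decelerating
    rt = _decelerating_arrival_case(cross_day=100.0, slow_start_day=30.0, n_days=50)
    assert (rt.data["lat"] > 45).all()
    assert detect_arrival(rt, departure=date(2022, 1, 1)) is None


def test_arrival_acceleration_gate():
    # monotonically accelerating south of 45: the derivative gate blocks it
    steps = 50 * 12
    t_day = np.arange(steps) / 12.0
    speed = 40.0 + 2.0 * t_day
    lat = 44.0 - np.cumsum(speed) / 12.0 / 111.19
    proj = LocalProjection(40.0, 0.0, "aeqd")
    x_km, y_km = proj.forward(lat, np.zeros(steps))
    from cachalot.ssm import RegularizedTrack

    df = pd.DataFrame(
        {
            "timestamp": pd.date_range("2022-01-01", periods=steps, freq="2h"),
            "lat": lat,
            "lon": 0.0,
            "x_km": x_km,
            "y_km": y_km,
            "sd_x_km": 0.1,
            "sd_y_km": 0.1,
            "segment_id": 0,
        }
    )
    rt = RegularizedTrack("acc", df, "segments_only", proj)
    curve = smoothed_speed_curve(rt)
    assert detect_arrival(rt, departure=date(2022, 1, 1), curve=curve) is None


def test_breeding_departure_crossing_mean_latitude():
    # roams at 40 degN, then heads north on day 141
    steps = 200 * 12
    day = np.arange(steps) / 12.0
    lat = np.where(day < 141, 40.0, 40.0 + (day - 141) * 1.0)
    proj = LocalProjection(45.0, 0.0, "aeqd")
    x, y = proj.forward(lat, np.zeros(steps))
    from cachalot.ssm import RegularizedTrack

    df = pd.DataFrame(
        {
            "timestamp": pd.date_range("2022-01-01", periods=steps, freq="2h"),
            "lat": lat,
            "lon": 0.0,
            "x_km": x,
            "y_km": y,
            "sd_x_km": 0.1,
            "sd_y_km": 0.1,
            "segment_id": 0,
        }
    )
    rt = RegularizedTrack("bd", df, "whole_track", proj)
    bdep = detect_breeding_departure(rt, date(2022, 1, 2), arrival_lats=[43.0, 41.0])
    # mean arrival latitude 42 first exceeded at day 141 + 2
    truth = date(2022, 1, 1) + pd.Timedelta(days=143)
    assert abs((bdep - truth).days) <= 1
    # single-animal cohort reduces to the animal's own arrival latitude
    own = detect_breeding_departure(rt, date(2022, 1, 2), arrival_lats=[40.5])
    assert own <= bdep
    # a whale whose record ends in the breeding area yields no departure
    rt_dead = RegularizedTrack("bd2", df[df["lat"] < 41.0].reset_index(drop=True), "whole_track", proj)
    assert detect_breeding_departure(rt_dead, date(2022, 1, 2), arrival_lats=[43.0]) is None


def test_return_north_first_reentry():
    rt = _southbound_rt(exit_day=10, n_days=80)
    # reverse the track: approaching from the south, entering the square
    df = rt.data.iloc[::-1].reset_index(drop=True)
    df["timestamp"] = pd.date_range("2022-06-01", periods=len(df), freq="2h")
    from cachalot.ssm import RegularizedTrack

    back = RegularizedTrack("ret", df, "whole_track", rt.projection)
    poly = _poly_square()
    ret = detect_return_north(back, poly, date(2022, 6, 1))
    inside = poly.contains(df["lat"].values, df["lon"].values)
    first = df["timestamp"][np.argmax(inside)].date()
    assert ret == first
    # no re-entry: the outbound track never comes back
    assert detect_return_north(rt, poly, date(2022, 3, 1)) is None


def test_polygon_vertex_counts_as_inside():
    poly = _poly_square()
    vlon, vlat = poly.vertices_lonlat[0]
    assert poly.contains([vlat], [vlon])[0]


# ---------------------------------------------------------------------------
# duration arithmetic


@pytest.mark.parametrize(
    "dates,expected",
    [
        # printed rows of the migration-summary table, checked by hand
        (
            (date(2023, 4, 4), date(2023, 5, 13), date(2023, 8, 23), date(2023, 9, 26)),
            (39, 102, 34, 175),
        ),
        (
            (date(2022, 10, 6), date(2022, 12, 8), date(2023, 3, 2), date(2023, 4, 4)),
            (63, 84, 33, 180),
        ),
    ],
)
def test_duration_arithmetic_whole_days(dates, expected):
    assert durations_from_dates(*dates) == expected


def test_duration_additivity():
    d = durations_from_dates(
        date(2022, 10, 6), date(2022, 12, 8), date(2023, 3, 2), date(2023, 4, 4)
    )
    assert d[0] + d[1] + d[2] == d[3]


def test_zero_length_leg_allowed():
    d = durations_from_dates(date(2022, 1, 1), date(2022, 1, 1), None, None)
    assert d[0] == 0


def test_out_of_order_dates_rejected():
    with pytest.raises(ValueError):
        durations_from_dates(date(2022, 5, 1), date(2022, 4, 1), None, None)
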