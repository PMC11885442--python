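import numpy as np
import pandas as pd
import pytest

from cachalot import (
    SegmentRules,
    SSMConfig,
    fit_ssm,
    loglik_ssm,
    predict_regular,
    segment_track,
    simulate_track,
    SimConfig,
)
from cachalot._geo import LocalProjection
from cachalot.track_io import RawLocation, Track

from conftest import make_track


# ---------------------------------------------------------------------------
# segmentation


def test_segment_track_no_gaps_single_window():
    t = make_track(np.arange(0, 241, 4), [70] * 61, [15] * 61)
    wins = segment_track(t)
    assert len(wins) == 1
    assert wins[0][0] == t.locations[0].timestamp
    assert wins[0][1] == t.locations[-1].timestamp


def test_segment_track_gap_splits_and_short_piece_dropped():
    # 10 d of 4-h fixes with an 80-h hole after day 5: the second piece of
    # ~1.7 d fails the 4-d minimum and is discarded
    hours = list(np.arange(0, 121, 4)) + list(np.arange(200, 241, 4))
    t = make_track(hours, [70] * len(hours), [15] * len(hours))
    wins = segment_track(t)
    assert len(wins) == 1
    assert (wins[0][1] - wins[0][0]).total_seconds() / 3600 == pytest.approx(120)


def test_segment_track_minimum_duration():
    t = make_track(np.arange(0, 72, 2), [70] * 36, [15] * 36)  # 3 d dense
    assert segment_track(t) == []


def test_segment_track_daily_coverage_rule():
    # a 60-h hole does not split (under 72 h) but leaves an uncovered
    # calendar date, so the window is discarded
    hours = list(np.arange(0, 37, 2)) + list(np.arange(96, 180, 2))
    t = make_track(hours, [70] * len(hours), [15] * len(hours))
    assert segment_track(t) == []


# ---------------------------------------------------------------------------
# likelihood and smoothing against dense-matrix oracles


def _dense_loglik(times, obs, r_var, sigma, m0, p0):
    t0 = times[0]
    C = p0 + sigma**2 * np.minimum.outer(times - t0, times - t0) + np.diag(r_var)
    resid = obs - m0
    _, logdet = np.linalg.slogdet(C)
    return -0.5 * (len(times) * np.log(2 * np.pi) + logdet + resid @ np.linalg.solve(C, resid))


def _dense_smooth(times, obs, r_var, sigma, m0, p0, tq):
    t0 = times[0]
    C = p0 + sigma**2 * np.minimum.outer(times - t0, times - t0) + np.diag(r_var)
    kq = p0 + sigma**2 * np.minimum(tq - t0, times - t0)
    return m0 + kq @ np.linalg.solve(C, obs - m0)


def _toy_track(n, seed=1, span_h=40.0):
    proj = LocalProjection(70.0, 15.0, "aeqd")
    rng = np.random.default_rng(seed)
    th = np.sort(rng.uniform(0, span_h, n))
    th[0] = 0.0
    xs = np.cumsum(rng.normal(0, 3, n))
    ys = np.cumsum(rng.normal(0, 3, n))
    lats, lons = proj.inverse(xs, ys)
    base = pd.Timestamp("2022-01-01")
    locs = [
        RawLocation("toy", base + pd.Timedelta(hours=float(h)), float(la), float(lo), "3")
        for h, la, lo in zip(th, lats, lons)
    ]
    return Track("toy", locs), th


def test_loglik_matches_dense_oracle():
    """Kalman log-likelihood equals the joint-Gaussian density on a 6-fix toy."""
    t, th = _toy_track(6)
    cfg = SSMConfig()
    sigma = 1.7
    proj = LocalProjection(70.0, 15.0, "aeqd")
    x, y = proj.forward(
        np.array([r.lat for r in t.locations]), np.array([r.lon for r in t.locations])
    )
    r_var = np.full(6, cfg.obs_sd_by_class["3"] ** 2)
    expected = _dense_loglik(th, x, r_var, sigma, x[0], cfg.prior_sd_km**2) + _dense_loglik(
        th, y, r_var, sigma, y[0], cfg.prior_sd_km**2
    )
    got = loglik_ssm(t, sigma, cfg, projection=proj)
    assert got == pytest.approx(expected, rel=1e-6)


def test_smoother_matches_gls_oracle():
    """Smoothed state means equal dense generalized-least-squares conditioning."""
    t, th = _toy_track(10)
    cfg = SSMConfig()
    fit = fit_ssm(t, cfg)
    rt = predict_regular(t, fit, cfg)
    x, y = fit.projection.forward(
        np.array([r.lat for r in t.locations]), np.array([r.lon for r in t.locations])
    )
    r_var = np.full(10, cfg.obs_sd_by_class["3"] ** 2)
    gh = (rt.data["timestamp"] - pd.Timestamp("2022-01-01")).dt.total_seconds().values / 3600
    for obs, col in ((x, "x_km"), (y, "y_km")):
        oracle = np.array(
            [_dense_smooth(th, obs, r_var, fit.sigma, obs[0], cfg.prior_sd_km**2, tq) for tq in gh]
        )
        scale = np.max(np.abs(oracle)) + 1.0
        assert np.max(np.abs(oracle - rt.data[col].values)) / scale < 1e-6


def test_sigma_recovery_dense_sampling():
    """ML estimate of the process scale within 15% on a 500-fix random walk."""
    rng = np.random.default_rng(7)
    sigma_true = 2.5
    n = 500
    th = np.arange(n) * 1.0
    proj = LocalProjection(70.0, 15.0, "aeqd")
    xs = np.cumsum(rng.normal(0, sigma_true, n))
    ys = np.cumsum(rng.normal(0, sigma_true, n))
    # small class-3 observation error
    lats, lons = proj.inverse(xs + rng.normal(0, 0.25, n), ys + rng.normal(0, 0.25, n))
    base = pd.Timestamp("2022-01-01")
    locs = [
        RawLocation("rw", base + pd.Timedelta(hours=float(h)), float(la), float(lo), "3")
        for h, la, lo in zip(th, lats, lons)
    ]
    fit = fit_ssm(Track("rw", locs))
    assert fit.sigma == pytest.approx(sigma_true, rel=0.15)


def test_identical_fixes_boundary_sigma():
    t = make_track(np.arange(0, 20, 2.0), [70] * 10, [15] * 10)
    fit = fit_ssm(t)
    assert fit.sigma < 0.01  # driven to the lower boundary without crashing


def test_zero_noise_limit_interpolates_fixes():
    """With near-zero observation SDs, predictions pass through the fixes."""
    t, th = _toy_track(8, seed=3)
    cfg = SSMConfig(obs_sd_by_class={c: 1e-4 for c in "3210AB"})
    fit = fit_ssm(t, cfg)
    rt = predict_regular(t, fit, cfg)
    for r in t.locations:
        sel = (rt.data["timestamp"] - r.timestamp).abs() < pd.Timedelta(seconds=1)
        if sel.any():
            row = rt.data[sel].iloc[0]
            assert row["lat"] == pytest.approx(r.lat, abs=1e-4)
            assert row["lon"] == pytest.approx(r.lon, abs=1e-4)


def test_brownian_bridge_midpoint():
    """Two fixes 4 h apart: the 2-h prediction is the planar midpoint."""
    proj = LocalProjection(70.0, 15.0, "aeqd")
    lats, lons = proj.inverse(np.array([0.0, 10.0]), np.array([0.0, 6.0]))
    base = pd.Timestamp("2022-01-01")
    locs = [
        RawLocation("b", base, float(lats[0]), float(lons[0]), "3"),
        RawLocation("b", base + pd.Timedelta(hours=4), float(lats[1]), float(lons[1]), "3"),
    ]
    t = Track("b", locs)
    cfg = SSMConfig(obs_sd_by_class={c: 1e-4 for c in "3210AB"})
    from cachalot.ssm import SSMFit

    fit = SSMFit(sigma=1.0, loglik=0.0, converged=True, projection=proj)
    rt = predict_regular(t, fit, cfg)
    mid = rt.data[rt.data["timestamp"] == base + pd.Timedelta(hours=2)].iloc[0]
    assert mid["x_km"] == pytest.approx(5.0, abs=1e-3)
    assert mid["y_km"] == pytest.approx(3.0, abs=1e-3)
    # interior uncertainty of the bridge: sigma^2 * t(T-t)/T = 1 per coord
    assert mid["sd_x_km"] == pytest.approx(1.0, abs=1e-3)
    # endpoints carry (almost) no uncertainty; the interior is maximal
    assert mid["sd_x_km"] >= rt.data["sd_x_km"].iloc[0]


def test_smoothed_variance_not_above_filtered(migrant_case):
    """RTS smoothing can only reduce the one-sided (filtered) uncertainty."""
    from cachalot.ssm import _kalman_filter_1d, _rts_smoother_1d

    rng = np.random.default_rng(5)
    n = 60
    th = np.sort(rng.uniform(0, 120, n))
    y = np.cumsum(rng.normal(0, 2, n))
    r_var = rng.uniform(0.3, 9.0, n)
    m_f, p_f, m_p, p_p, _ = _kalman_filter_1d(th, y, r_var, 1.5, y[0], 1e6)
    m_s, p_s = _rts_smoother_1d(th, m_f, p_f, m_p, p_p)
    assert np.all(p_s <= p_f + 1e-9)


def test_whole_track_spans_gaps_segments_only_does_not(migrant_case):
    whole = migrant_case["whole"]
    segs = migrant_case["segments"]
    assert len(whole) >= len(segs)
    # segments dataset: timestamps equally spaced within each segment
    for _, grp in segs.data.groupby("segment_id"):
        dt = np.diff(grp["timestamp"].values).astype("timedelta64[s]").astype(float)
        assert np.allclose(dt, 7200.0)
    # whole-track grid covers the full record at the 2-h step
    expected = (
        migrant_case["filtered"].locations[-1].timestamp
        - migrant_case["filtered"].locations[0].timestamp
    ).total_seconds() // 7200 + 1
    assert len(whole) == pytest.approx(expected, rel=0.01)
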