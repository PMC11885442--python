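"""Continuous-time random-walk state-space model for Argos tracks.

The latent path is 2-D Brownian motion with a single process scale sigma
(km per sqrt-hour), observed at irregular surfacing times with isotropic
Gaussian error whose SD depends on the Argos location class. Fitting and
smoothing run in a local azimuthal-equidistant plane centred on the track
(a random walk written directly in lat/lon degrees is badly distorted at
the 69-79 degN tagging latitudes), and predictions are re-inverted to
lat/lon. Because the error model is isotropic, the two planar coordinates
decouple into independent scalar Kalman recursions sharing sigma.

Tracks are regularized in two flavours, mirroring how the analysis uses
them downstream:

* ``whole_track`` — one model over the full record, predicting across
  transmission gaps (with correspondingly inflated uncertainty); used for
  cumulative distances and migration timing.
* ``segments_only`` — predictions only inside well-sampled segments
  (split at gaps > 72 h; at least 4 d long; every calendar date covered),
  used for behavioural metrics where gap-spanning interpolation would
  fabricate movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._geo import LocalProjection
from .track_io import Track


@dataclass(frozen=True)
class SSMConfig:
    dt_pred_h: float = 2.0
    # literature-typical isotropic Argos error SDs per class, km
    obs_sd_by_class: dict = field(
        default_factory=lambda: {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 5.0, "B": 10.0}
    )
    process_sd_init: float = 2.0  # km / sqrt(h)
    prior_sd_km: float = 1000.0  # SD of the diffuse-ish initial state
    optimizer_tol: float = 1e-6

    def __post_init__(self):
        if self.dt_pred_h <= 0:
            raise ValueError("dt_pred must be positive")
        if any(v <= 0 for v in self.obs_sd_by_class.values()):
            raise ValueError("observation SDs must be positive")


@dataclass(frozen=True)
class SegmentRules:
    max_gap_h: float = 72.0
    min_segment_duration_d: float = 4.0
    min_locs_per_day: int = 1


@dataclass(frozen=True)
class SSMFit:
    sigma: float  # process SD, km / sqrt(h)
    loglik: float
    converged: bool
    projection: LocalProjection


class SSMNotConverged(RuntimeError):
    """Optimizer failure; carries the best parameters found so far."""

    def __init__(self, msg: str, best_fit: SSMFit):
        super().__init__(msg)
        self.best_fit = best_fit


@dataclass
class RegularizedTrack:
    """State-space positions predicted on a regular grid.

    ``data`` columns: timestamp, lat, lon, x_km, y_km, sd_x_km, sd_y_km,
    segment_id. Timestamps are equally spaced within a segment.
    """

    animal_id: str
    data: pd.DataFrame
    dataset_kind: str  # "whole_track" | "segments_only"
    projection: LocalProjection

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# segmentation


def segment_track(t: Track, rules: SegmentRules = SegmentRules()) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Split a track at transmission gaps and keep well-sampled windows.

    The track is cut at every inter-fix gap exceeding ``max_gap_h`` and
    wherever a gap leaves a whole calendar date without a fix, so every
    surviving segment has at least one position per spanned day. Windows
    shorter than ``min_segment_duration_d`` days are discarded, as are
    windows containing a date with fewer than ``min_locs_per_day`` fixes
    (relevant only for thresholds above one).
    """
    times = pd.Series([r.timestamp for r in t.locations])
    if times.empty:
        return []
    gaps_h = times.diff().dt.total_seconds() / 3600.0
    date_jump = pd.Series([d.toordinal() for d in times.dt.date]).diff()
    cut = (gaps_h > rules.max_gap_h) | (date_jump >= 2)  # >=1 empty date between fixes
    window_id = cut.cumsum().fillna(0)
    windows: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for _, grp in times.groupby(window_id):
        start, end = grp.iloc[0], grp.iloc[-1]
        if (end - start).total_seconds() / 86400.0 < rules.min_segment_duration_d:
            continue
        if rules.min_locs_per_day > 1:
            counts = grp.dt.date.value_counts()
            span = pd.date_range(start.date(), end.date(), freq="D").date
            if any(counts.get(d, 0) < rules.min_locs_per_day for d in span):
                continue
        windows.append((start, end))
    return windows


# ---------------------------------------------------------------------------
# Kalman machinery (scalar; the two planar coordinates are independent)


def _kalman_filter_1d(times_h, y, r_var, sigma, m0, p0):
    """Forward filter over possibly-missing observations.

    ``y`` may contain NaN (no observation at that node). Returns filtered
    means/variances, one-step predicted means/variances, and the log-likelihood
    of the non-missing observations.
    """
    n = len(times_h)
    m_f = np.empty(n)
    p_f = np.empty(n)
    m_p = np.empty(n)
    p_p = np.empty(n)
    ll = 0.0
    m, p = m0, p0
    prev_t = times_h[0]
    for i in range(n):
        dt = times_h[i] - prev_t
        p = p + sigma * sigma * dt
        m_p[i], p_p[i] = m, p
        if not np.isnan(y[i]):
            s = p + r_var[i]
            innov = y[i] - m
            ll += -0.5 * (np.log(2.0 * np.pi * s) + innov * innov / s)
            k = p / s
            m = m + k * innov
            p = (1.0 - k) * p
        m_f[i], p_f[i] = m, p
        prev_t = times_h[i]
    return m_f, p_f, m_p, p_p, ll


def _rts_smoother_1d(times_h, m_f, p_f, m_p, p_p):
    n = len(times_h)
    m_s = m_f.copy()
    p_s = p_f.copy()
    for i in range(n - 2, -1, -1):
        if p_p[i + 1] <= 0:
            continue
        g = p_f[i] / p_p[i + 1]
        m_s[i] = m_f[i] + g * (m_s[i + 1] - m_p[i + 1])
        p_s[i] = p_f[i] + g * g * (p_s[i + 1] - p_p[i + 1])
    return m_s, p_s


def _track_arrays(t: Track, cfg: SSMConfig, proj: LocalProjection):
    times = np.array([r.timestamp.value for r in t.locations], dtype=np.int64) / 3.6e12
    lat = np.array([r.lat for r in t.locations])
    lon = np.array([r.lon for r in t.locations])
    x, y = proj.forward(lat, lon)
    sd = np.array([cfg.obs_sd_by_class[r.loc_class] for r in t.locations])
    return times, x, y, sd


def loglik_ssm(t: Track, sigma: float, cfg: SSMConfig = SSMConfig(),
               projection: LocalProjection | None = None) -> float:
    """Exact log-likelihood of a track under the model at a given sigma."""
    proj = projection or _centroid_projection(t)
    times, x, y, sd = _track_arrays(t, cfg, proj)
    r_var = sd * sd
    p0 = cfg.prior_sd_km**2
    ll = 0.0
    for obs in (x, y):
        *_, l = _kalman_filter_1d(times, obs, r_var, sigma, obs[0], p0)
        ll += l
    return ll


def _centroid_projection(t: Track) -> LocalProjection:
    lat = np.mean([r.lat for r in t.locations])
    lon = np.mean([r.lon for r in t.locations])
    return LocalProjection(lat, lon, kind="aeqd")


def fit_ssm(t: Track, cfg: SSMConfig = SSMConfig()) -> SSMFit:
    """Maximum-likelihood estimate of the process scale sigma (km/sqrt-h)."""
    if len(t) < 5:
        raise ValueError(f"track {t.animal_id}: need >=5 fixes to fit the SSM")
    proj = _centroid_projection(t)
    times, x, y, sd = _track_arrays(t, cfg, proj)
    r_var = sd * sd
    p0 = cfg.prior_sd_km**2

    def nll(log_sigma: float) -> float:
        s = np.exp(log_sigma)
        ll = 0.0
        for obs in (x, y):
            *_, l = _kalman_filter_1d(times, obs, r_var, s, obs[0], p0)
            ll += l
        return -ll

    res = minimize_scalar(
        nll, bounds=(np.log(1e-4), np.log(1e3)), method="bounded",
        options={"xatol": cfg.optimizer_tol},
    )
    sigma = float(np.exp(res.x))
    fit = SSMFit(sigma=sigma, loglik=float(-res.fun), converged=bool(res.success), projection=proj)
    if not res.success:
        raise SSMNotConverged(f"SSM optimizer failed on track {t.animal_id}", fit)
    return fit


def _grid_times(t0: pd.Timestamp, start: pd.Timestamp, end: pd.Timestamp, dt_h: float):
    """Regular grid (anchored at the track start) covering [start, end]."""
    step = pd.Timedelta(hours=dt_h)
    k0 = int(np.ceil((start - t0) / step - 1e-9))
    k1 = int(np.floor((end - t0) / step + 1e-9))
    return [t0 + i * step for i in range(k0, k1 + 1)]


def predict_regular(
    t: Track,
    fit: SSMFit,
    cfg: SSMConfig = SSMConfig(),
    windows: Sequence[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
    dataset_kind: str = "whole_track",
) -> RegularizedTrack:
    """RTS-smoothed positions at every grid point inside each window.

    ``whole_track`` predicts across gaps with one model pass over the full
    record; ``segments_only`` runs an independent pass per window using only
    the fixes inside it.
    """
    proj = fit.projection
    times_all, x_all, y_all, sd_all = _track_arrays(t, cfg, proj)
    ts_all = pd.Series([r.timestamp for r in t.locations])
    t0 = ts_all.iloc[0]

    if windows is None:
        windows = [(ts_all.iloc[0], ts_all.iloc[-1])]
    if dataset_kind == "whole_track":
        passes = [(windows, np.ones(len(t), dtype=bool))]
    elif dataset_kind == "segments_only":
        passes = [
            ([w], (ts_all >= w[0]).values & (ts_all <= w[1]).values) for w in windows
        ]
    else:
        raise ValueError(f"unknown dataset_kind {dataset_kind!r}")

    frames = []
    seg_id = 0
    for wins, mask in passes:
        if mask.sum() < 2:
            warnings.warn(f"track {t.animal_id}: window with <2 fixes skipped", stacklevel=2)
            continue
        obs_t = times_all[mask]
        obs_x, obs_y, obs_sd = x_all[mask], y_all[mask], sd_all[mask]
        grid = []
        grid_seg = []
        for w in wins:
            gt = _grid_times(t0, max(w[0], ts_all.iloc[0]), min(w[1], ts_all.iloc[-1]), cfg.dt_pred_h)
            grid.extend(gt)
            grid_seg.extend([seg_id] * len(gt))
            seg_id += 1
        if not grid:
            continue
        grid_h = np.array([g.value for g in grid], dtype=np.int64) / 3.6e12

        # merge observation and grid nodes on a common time axis
        node_t = np.concatenate([obs_t, grid_h])
        node_y_x = np.concatenate([obs_x, np.full(len(grid_h), np.nan)])
        node_y_y = np.concatenate([obs_y, np.full(len(grid_h), np.nan)])
        node_r = np.concatenate([obs_sd**2, np.ones(len(grid_h))])
        is_grid = np.concatenate([np.full(len(obs_t), -1), np.arange(len(grid_h))])
        order = np.argsort(node_t, kind="stable")
        node_t, node_y_x, node_y_y = node_t[order], node_y_x[order], node_y_y[order]
        node_r, is_grid = node_r[order], is_grid[order]

        p0 = cfg.prior_sd_km**2
        out = {}
        for label, obs in (("x", node_y_x), ("y", node_y_y)):
            m_f, p_f, m_p, p_p, _ = _kalman_filter_1d(
                node_t, obs, node_r, fit.sigma, obs[~np.isnan(obs)][0], p0
            )
            m_s, p_s = _rts_smoother_1d(node_t, m_f, p_f, m_p, p_p)
            out[label] = (m_s, p_s)

        sel = is_grid >= 0
        gx, gpx = out["x"][0][sel], out["x"][1][sel]
        gy, gpy = out["y"][0][sel], out["y"][1][sel]
        gi = is_grid[sel].astype(int)
        lat, lon = proj.inverse(gx, gy)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": np.array(grid, dtype="datetime64[ns]")[gi],
                    "lat": lat,
                    "lon": lon,
                    "x_km": gx,
                    "y_km": gy,
                    "sd_x_km": np.sqrt(np.maximum(gpx, 0.0)),
                    "sd_y_km": np.sqrt(np.maximum(gpy, 0.0)),
                    "segment_id": np.array(grid_seg)[gi],
                }
            )
        )

    data = (
        pd.concat(frames, ignore_index=True).sort_values("timestamp").reset_index(drop=True)
        if frames
        else pd.DataFrame(
            columns=["timestamp", "lat", "lon", "x_km", "y_km", "sd_x_km", "sd_y_km", "segment_id"]
        )
    )
    return RegularizedTrack(t.animal_id, data, dataset_kind, proj)
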