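"""Movement metrics on regularized tracks: speed, bearing, distances, and
the move-persistence behavioural index.

Speed is the straight-line displacement between consecutive 2-h modelled
positions divided by the 2-h step, computed on segments only — interpolating
across transmission gaps would dilute it. This is an acknowledged
underestimate of the true 3-D movement. Cumulative distance runs over the
whole track, bridging segment joins with a straight line.

Move persistence gamma_t in (0, 1) measures autocorrelation in both speed
and direction: the expected displacement vector at step t is gamma_t times
the previous displacement plus isotropic noise, and logit(gamma_t) follows
a Gaussian random walk. Values near 1 indicate directed transit; values
near 0 indicate variable movement in a restricted area. Estimation is by
Laplace-approximated marginal likelihood: the inner mode over the logit
series is found by damped Newton steps on a banded (tridiagonal) Hessian,
and the two variance parameters — the step-noise SD and the random-walk SD
of logit(gamma), the latter pooled across animals in a joint fit — are
optimized by Nelder-Mead on the Laplace objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky_banded, solveh_banded
from scipy.special import expit
from scipy.optimize import minimize

from ._geo import haversine_km, initial_bearing_deg
from .ssm import RegularizedTrack

__all__ = [
    "great_circle_km",
    "bearing_deg",
    "step_metrics",
    "PersistenceSeries",
    "fit_move_persistence",
]


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    return float(haversine_km(a[0], a[1], b[0], b[1]))


def bearing_deg(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Initial great-circle azimuth a -> b, degrees clockwise from north."""
    return float(initial_bearing_deg(a[0], a[1], b[0], b[1]))


def step_metrics(rt: RegularizedTrack, migration_start: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-step displacement, speed, cumulative distance, and bearing.

    Speeds are defined only for consecutive grid points within the same
    segment; cumulative distance accumulates across segment joins as well
    (linear bridging, an acknowledged underestimate). When
    ``migration_start`` is given, each position also carries the initial
    great-circle bearing from that point.
    """
    df = rt.data
    if len(df) < 2:
        return pd.DataFrame(
            columns=["timestamp", "segment_id", "displacement_km", "speed_kmh",
                     "cumulative_distance_km", "bearing_deg"]
        )
    lat, lon = df["lat"].values, df["lon"].values
    d = np.concatenate([[0.0], haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])])
    dt_h = np.concatenate(
        [[np.nan], np.diff(df["timestamp"].values).astype("timedelta64[s]").astype(float) / 3600.0]
    )
    same_seg = np.concatenate([[False], df["segment_id"].values[1:] == df["segment_id"].values[:-1]])
    speed = np.where(same_seg, d / dt_h, np.nan)
    out = pd.DataFrame(
        {
            "timestamp": df["timestamp"],
            "segment_id": df["segment_id"],
            "displacement_km": np.where(same_seg, d, np.nan),
            "speed_kmh": speed,
            "cumulative_distance_km": np.cumsum(d),
        }
    )
    if migration_start is not None:
        out["bearing_deg"] = initial_bearing_deg(
            migration_start[0], migration_start[1], lat, lon
        )
    else:
        out["bearing_deg"] = np.nan
    return out


# ---------------------------------------------------------------------------
# move persistence


@dataclass
class PersistenceSeries:
    """Per-step gamma estimates for one animal plus the fitted variances."""

    animal_id: str
    data: pd.DataFrame  # timestamp, segment_id, gamma
    step_sd_km: float
    logit_rw_sd: float
    loglik: float


def _displacement_chains(rt: RegularizedTrack, min_steps: int):
    """Displacement-vector chains (one per long-enough segment)."""
    chains = []
    for seg, grp in rt.data.groupby("segment_id"):
        if len(grp) < min_steps:
            continue
        dx = np.diff(grp["x_km"].values)
        dy = np.diff(grp["y_km"].values)
        # gamma_t relates step t to step t-1: n_steps-1 gamma values
        if len(dx) < 2:
            continue
        chains.append((seg, grp["timestamp"].values[2:], np.column_stack([dx, dy])))
    return chains


def _inner_objective(g, d, sd2_step):
    """Joint negative log-density terms that depend on the logit series g."""
    gam = expit(g)
    prev, cur = d[:-1], d[1:]
    resid = cur - gam[:, None] * prev
    data_term = 0.5 * np.sum(resid**2) / sd2_step
    return data_term, gam, resid


def _newton_mode(d, sd2_step, sd2_rw, max_iter=100, tol=1e-10):
    """Mode and banded Hessian of the joint density over g = logit(gamma)."""
    n = d.shape[0] - 1  # number of gamma values
    g = np.zeros(n)
    prev = d[:-1]
    prev_sq = np.sum(prev**2, axis=1)

    def objective(g):
        data_term, _, _ = _inner_objective(g, d, sd2_step)
        rw_term = 0.5 * np.sum(np.diff(g) ** 2) / sd2_rw if n > 1 else 0.0
        return data_term + rw_term

    f = objective(g)
    for _ in range(max_iter):
        gam = expit(g)
        dgam = gam * (1.0 - gam)
        resid = d[1:] - gam[:, None] * prev
        # gradient of data term wrt g
        grad = -(np.sum(resid * prev, axis=1) / sd2_step) * dgam
        # Gauss-Newton diagonal (positive semi-definite) for the data term
        hess_diag = (prev_sq / sd2_step) * dgam**2
        if n > 1:
            dg = np.diff(g)
            grad[:-1] -= dg / sd2_rw
            grad[1:] += dg / sd2_rw
            hess_diag = hess_diag.copy()
            hess_diag[0] += 1.0 / sd2_rw
            hess_diag[-1] += 1.0 / sd2_rw
            hess_diag[1:-1] += 2.0 / sd2_rw
            off = np.full(n - 1, -1.0 / sd2_rw)
        else:
            off = np.zeros(0)
        ab = np.zeros((2, n))
        ab[0, 1:] = off
        ab[1, :] = hess_diag + 1e-12
        step = solveh_banded(ab, -grad)
        # backtracking line search
        alpha = 1.0
        for _ in range(30):
            g_new = g + alpha * step
            f_new = objective(g_new)
            if f_new <= f + 1e-12:
                break
            alpha *= 0.5
        if f - f_new < tol * (1.0 + abs(f)):
            g, f = g_new, f_new
            break
        g, f = g_new, f_new
    # final banded Hessian at the mode
    gam = expit(g)
    dgam = gam * (1.0 - gam)
    hess_diag = (prev_sq / sd2_step) * dgam**2
    if n > 1:
        hess_diag = hess_diag.copy()
        hess_diag[0] += 1.0 / sd2_rw
        hess_diag[-1] += 1.0 / sd2_rw
        hess_diag[1:-1] += 2.0 / sd2_rw
        off = np.full(n - 1, -1.0 / sd2_rw)
    else:
        off = np.zeros(0)
    ab = np.zeros((2, n))
    ab[0, 1:] = off
    ab[1, :] = hess_diag + 1e-10
    return g, f, ab


def _laplace_nll(theta, chains):
    """Negative Laplace-approximate marginal log-likelihood, all chains."""
    log_sd_step, log_sd_rw = theta
    sd2_step = np.exp(2.0 * log_sd_step)
    sd2_rw = np.exp(2.0 * log_sd_rw)
    nll = 0.0
    modes = []
    for _, _, d in chains:
        n = d.shape[0] - 1
        g, f_mode, ab = _newton_mode(d, sd2_step, sd2_rw)
        # Gaussian normalizing constants: 2n data dims, n-1 RW increments
        const = n * np.log(2.0 * np.pi * sd2_step)
        if n > 1:
            const += 0.5 * (n - 1) * np.log(2.0 * np.pi * sd2_rw)
        chol = cholesky_banded(ab, lower=False)
        logdet = 2.0 * np.sum(np.log(chol[-1]))
        nll += f_mode + const + 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi)
        modes.append(g)
    return nll, modes


def fit_move_persistence(
    rts: RegularizedTrack | list[RegularizedTrack],
    min_steps: int = 20,
) -> list[PersistenceSeries]:
    """Estimate time-varying move persistence on 2-h segments.

    Accepts one regularized track or several; with several, the variance
    parameters (step-noise SD and the logit-scale random-walk SD) are pooled
    across animals so gamma is comparable between individuals. Segments with
    fewer than ``min_steps`` grid points are skipped.
    """
    tracks = [rts] if isinstance(rts, RegularizedTrack) else list(rts)
    per_track = [(rt, _displacement_chains(rt, min_steps)) for rt in tracks]
    all_chains = [c for _, chains in per_track for c in chains]
    if not all_chains:
        raise ValueError("no segment with enough regular steps for move persistence")

    # moment-based initialization of the step-noise SD
    d0 = np.concatenate([d for _, _, d in all_chains])
    sd0 = max(np.std(np.diff(d0, axis=0)) / np.sqrt(2.0), 1e-3)
    theta0 = np.array([np.log(sd0), np.log(0.2)])

    res = minimize(
        lambda th: _laplace_nll(th, all_chains)[0],
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("move-persistence optimizer failed to converge")
    nll, modes = _laplace_nll(res.x, all_chains)
    sd_step = float(np.exp(res.x[0]))
    sd_rw = float(np.exp(res.x[1]))

    out: list[PersistenceSeries] = []
    i = 0
    for rt, chains in per_track:
        rows = []
        for (seg, ts, d), g in zip(chains, modes[i : i + len(chains)]):
            gam = expit(g)
            rows.append(pd.DataFrame({"timestamp": ts, "segment_id": seg, "gamma": gam}))
        i += len(chains)
        data = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["timestamp", "segment_id", "gamma"])
        )
        out.append(PersistenceSeries(rt.animal_id, data, sd_step, sd_rw, float(-nll)))
    return out
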