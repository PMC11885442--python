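"""Speed/distance/angle (SDA) plausibility filter.

Removes Argos fixes that imply impossible swimming speeds (default bound
5 m s^-1) or sharp out-and-back "spikes" (turning angle below 15 deg with
both adjacent legs longer than 2,500 m, or below 25 deg with both legs
longer than 5,000 m). The filter iterates to a fixed point, removing the
single worst offender (highest implied speed, then smallest angle) per
pass; first and last fixes are always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geo import haversine_km
from .track_io import RawLocation, Track


@dataclass(frozen=True)
class FilterConfig:
    vmax_ms: float = 5.0
    spike_angles_deg: tuple[float, float] = (15.0, 25.0)
    spike_dist_limits_m: tuple[float, float] = (2500.0, 5000.0)
    # Pairs separated by more than this are exempt from the speed test: over
    # a multi-day gap the straight-line speed bound carries no information.
    speed_exempt_gap_h: float = 24.0

    def __post_init__(self):
        if self.vmax_ms <= 0:
            raise ValueError("vmax must be positive")
        a1, a2 = self.spike_angles_deg
        d1, d2 = self.spike_dist_limits_m
        if not (0 < a1 < 180 and 0 < a2 < 180):
            raise ValueError("spike angles must be in (0, 180) degrees")
        if not (0 < d1 < d2):
            raise ValueError("spike distances must be positive and increasing")


@dataclass(frozen=True)
class RemovedFix:
    location: RawLocation
    reason: str  # "speed" | "spike"


def sda_filter(t: Track, cfg: FilterConfig = FilterConfig()) -> tuple[Track, list[RemovedFix]]:
    """Apply the speed/distance/angle filter to a cleaned track.

    Returns the filtered track and the removed fixes, each tagged with the
    rule ("speed" or "spike") that removed it. The result is a fixed point:
    re-filtering removes nothing further, and every retained consecutive
    pair (not separated by an exempting gap) implies a speed <= vmax.
    """
    if len(t) < 3:
        warnings.warn(f"track {t.animal_id}: <3 fixes, SDA filter skipped", stacklevel=2)
        return t, []

    lat0 = np.array([r.lat for r in t.locations])
    lon0 = np.array([r.lon for r in t.locations])
    ts0 = np.array([r.timestamp.value for r in t.locations], dtype=np.int64) / 1e9
    keep = np.ones(len(t), dtype=bool)
    removed: list[RemovedFix] = []

    while True:
        idx = np.nonzero(keep)[0]
        n = len(idx)
        if n < 3:
            break
        lat, lon, ts = lat0[idx], lon0[idx], ts0[idx]
        leg_km = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt_s = np.maximum(np.diff(ts), 1e-9)
        v_ms = leg_km * 1000.0 / dt_s
        active = dt_s / 3600.0 <= cfg.speed_exempt_gap_h

        # interior fixes i = 1..n-2: min implied speed to retained neighbours
        v_prev = np.where(active[: n - 2], v_ms[: n - 2], 0.0)
        v_next = np.where(active[1 : n - 1], v_ms[1 : n - 1], 0.0)
        vmin = np.minimum(v_prev, v_next)
        speed_bad = vmin > cfg.vmax_ms

        # turning angle at interior fixes (planar cosine rule on great-circle
        # leg lengths; ample at these scales)
        ab = leg_km[: n - 2]
        bc = leg_km[1 : n - 1]
        ac = haversine_km(lat[: n - 2], lon[: n - 2], lat[2:], lon[2:])
        denom = np.maximum(2.0 * ab * bc, 1e-12)
        cosang = np.clip((ab**2 + bc**2 - ac**2) / denom, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        ang = np.where((ab < 1e-9) | (bc < 1e-9), 180.0, ang)
        spike_bad = np.zeros(n - 2, dtype=bool)
        for ang_lim, dist_lim in zip(cfg.spike_angles_deg, cfg.spike_dist_limits_m):
            spike_bad |= (ang < ang_lim) & (ab * 1000.0 > dist_lim) & (bc * 1000.0 > dist_lim)
        spike_bad &= ~speed_bad

        if speed_bad.any() or spike_bad.any():
            vmax_pair = np.maximum(v_ms[: n - 2], v_ms[1 : n - 1])
            score_speed = np.where(speed_bad, vmin, -np.inf)
            score_spike = np.where(spike_bad, vmax_pair, -np.inf)
            # highest implied speed wins; among spikes, smaller angle breaks ties
            if score_speed.max() >= score_spike.max():
                j = int(np.argmax(score_speed))
                reason = "speed"
            else:
                best = score_spike.max()
                cand = np.nonzero(score_spike >= best - 1e-12)[0]
                j = int(cand[np.argmin(ang[cand])])
                reason = "spike"
            g = idx[j + 1]
        else:
            # enforce the pairwise bound: a retained non-gap pair must not
            # imply a speed above vmax (rare after the min-speed rule)
            pair_bad = np.nonzero(active & (v_ms > cfg.vmax_ms))[0]
            pair_bad = pair_bad[(pair_bad > 0) | (pair_bad < n - 2)]
            if len(pair_bad) == 0:
                break
            j = int(pair_bad[np.argmax(v_ms[pair_bad])])
            # remove the interior endpoint of the offending pair
            g = idx[j + 1] if j + 1 < n - 1 else idx[j]
            if g == idx[0] or g == idx[-1]:
                break
            reason = "speed"
        keep[g] = False
        removed.append(RemovedFix(t.locations[g], "speed" if reason == "speed" else "spike"))

    kept = [r for r, k in zip(t.locations, keep) if k]
    return Track(t.animal_id, kept, t.tagging_location, t.tagging_date), removed
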