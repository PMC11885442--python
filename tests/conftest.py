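import numpy as np
import pandas as pd
import pytest

from cachalot import (
    RawLocation,
    SimConfig,
    Track,
    clean_track,
    fit_ssm,
    predict_regular,
    sda_filter,
    segment_track,
    simulate_track,
)
from cachalot._geo import LocalProjection
from cachalot.ssm import RegularizedTrack


def make_track(times_h, lats, lons, classes=None, animal_id="t1",
               base="2022-01-01") -> Track:
    base = pd.Timestamp(base)
    classes = classes or ["3"] * len(times_h)
    locs = [
        RawLocation(animal_id, base + pd.Timedelta(hours=float(h)), float(la), float(lo), c)
        for h, la, lo, c in zip(times_h, lats, lons, classes)
    ]
    return Track(animal_id, locs)


def make_regularized(xy_km, animal_id="rt", center=(70.0, 15.0), dt_h=2.0,
                     segment_id=None, base="2022-01-01", kind="aeqd") -> RegularizedTrack:
    """Wrap planar positions (n, 2) into a RegularizedTrack on a 2-h grid."""
    xy = np.asarray(xy_km, dtype=float)
    proj = LocalProjection(*center, kind=kind)
    lat, lon = proj.inverse(xy[:, 0], xy[:, 1])
    ts = pd.date_range(base, periods=len(xy), freq=f"{int(dt_h * 60)}min")
    df = pd.DataFrame(
        {
            "timestamp": ts,
            "lat": lat,
            "lon": lon,
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "sd_x_km": 0.1,
            "sd_y_km": 0.1,
            "segment_id": segment_id if segment_id is not None else 0,
        }
    )
    return RegularizedTrack(animal_id, df, "segments_only", proj)


@pytest.fixture(scope="session")
def migrant_case():
    """One simulated migrant pushed through filter + SSM (shared, read-only)."""
    cfg = SimConfig(seed=42)
    track, truth = simulate_track(cfg, "mig-fixture", migrant=True)
    cleaned = clean_track(track)
    filtered, removed = sda_filter(cleaned)
    fit = fit_ssm(filtered)
    whole = predict_regular(filtered, fit)
    windows = segment_track(filtered)
    segs = predict_regular(filtered, fit, windows=windows, dataset_kind="segments_only")
    return {
        "cfg": cfg,
        "track": track,
        "truth": truth,
        "cleaned": cleaned,
        "filtered": filtered,
        "removed": removed,
        "fit": fit,
        "whole": whole,
        "segments": segs,
        "windows": windows,
    }
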