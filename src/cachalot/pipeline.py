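"""End-to-end orchestration: filter, regularize, measure, date, summarize.

Every stage writes plain CSV (or GeoJSON) into the run directory so any
step can be inspected or rerun in isolation; a MANIFEST lists each artifact
with a content hash. Given the same inputs and seed, a rerun is
numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dives as dv
from . import phenology as ph
from .metrics import fit_move_persistence, step_metrics
from .prefilter import FilterConfig, sda_filter
from .ssm import SegmentRules, SSMConfig, fit_ssm, predict_regular, segment_track
from .synth import SimConfig, simulate_cohort, simulate_dives
from .track_io import Track, clean_track, track_meta, write_locations
from .tsa import accumulate_tsa, tsa_summary

log = logging.getLogger("cachalot")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 1
    filter: FilterConfig = field(default_factory=FilterConfig)
    ssm: SSMConfig = field(default_factory=SSMConfig)
    segments: SegmentRules = field(default_factory=SegmentRules)
    migrant_threshold_km: float = ph.MIGRANT_THRESHOLD_KM
    breeding_lat_limit: float = ph.BREEDING_LAT_LIMIT
    loess_span: float | None = None  # None -> documented default 0.2
    cell_km: float = 50.0
    tsa_exclude_ids: tuple[str, ...] = ()
    fit_persistence: bool = False  # costly; off by default in the smoke path

    def resolved_loess_span(self) -> float:
        if self.loess_span is None:
            log.warning("loess span not set; falling back to default 0.2")
            return ph.LOESS_SPAN
        return self.loess_span


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    run_dir: Path
    records: list
    cohort: dict
    regularized: dict  # animal_id -> (whole, segments)
    foraging_poly: object | None = None


def run_pipeline(cfg: PipelineConfig, tracks: list[Track],
                 single_dives: dict[str, list] | None = None,
                 dive_cfg=dv.CONFIG_B) -> PipelineResult:
    """Run every analysis stage on cleaned-or-raw input tracks."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    span = cfg.resolved_loess_span()

    cleaned = [clean_track(t) for t in tracks]
    meta_rows = []
    for t in cleaned:
        m = track_meta(t)
        meta_rows.append({"id": t.animal_id, **vars(m)})
    pd.DataFrame(meta_rows).to_csv(run_dir / "track_meta.csv", index=False)

    filtered = []
    removed_rows = []
    for t in cleaned:
        ft, removed = sda_filter(t, cfg.filter)
        filtered.append(ft)
        removed_rows += [
            {"id": r.location.animal_id, "timestamp": r.location.timestamp,
             "lat": r.location.lat, "lon": r.location.lon, "reason": r.reason}
            for r in removed
        ]
    pd.DataFrame(removed_rows).to_csv(run_dir / "removed_fixes.csv", index=False)
    write_locations(filtered, run_dir / "filtered_locations.csv")

    # classification uses the cleaned tracks; the polygon uses non-migrants
    flags = {t.animal_id: ph.classify_migrant(t, cfg.migrant_threshold_km) for t in cleaned}
    non_migrants = [t for t in cleaned if not flags[t.animal_id][0]]
    poly = ph.foraging_polygon(non_migrants) if len(non_migrants) >= 1 else None
    if poly is not None:
        (run_dir / "foraging_polygon.geojson").write_text(json.dumps({
            "type": "Feature",
            "properties": {"area_km2": poly.area_km2},
            "geometry": {"type": "Polygon", "coordinates": [poly.vertices_lonlat]},
        }))

    regularized = {}
    reg_rows = []
    for t in filtered:
        if len(t) < 5:
            log.warning("track %s too short for the SSM; skipped", t.animal_id)
            continue
        fit = fit_ssm(t, cfg.ssm)
        windows = segment_track(t, cfg.segments)
        whole = predict_regular(t, fit, cfg.ssm, dataset_kind="whole_track")
        segs = predict_regular(t, fit, cfg.ssm, windows=windows, dataset_kind="segments_only")
        regularized[t.animal_id] = (whole, segs)
        for kind, rt in (("whole_track", whole), ("segments_only", segs)):
            df = rt.data.copy()
            df.insert(0, "id", t.animal_id)
            df["dataset_kind"] = kind
            reg_rows.append(df)
    if reg_rows:
        pd.concat(reg_rows, ignore_index=True).to_csv(run_dir / "regularized.csv", index=False)

    records = []
    arrival_lats = []
    events = {}
    for t in filtered:
        if t.animal_id not in regularized:
            continue
        whole, segs = regularized[t.animal_id]
        migrant, dmax = flags[t.animal_id]
        start = arrival = None
        if migrant and poly is not None:
            start = ph.detect_departure(whole, poly, cfg.breeding_lat_limit)
            if start is not None:
                arrival = ph.detect_arrival(segs, start, lat_limit=cfg.breeding_lat_limit, span=span)
        events[t.animal_id] = {"start": start, "arrival": arrival}
        if arrival is not None:
            alat = ph.arrival_latitude(whole, arrival)
            if alat is not None:
                arrival_lats.append(alat)

    for t in filtered:
        if t.animal_id not in regularized:
            continue
        whole, segs = regularized[t.animal_id]
        migrant, dmax = flags[t.animal_id]
        ev = events[t.animal_id]
        bdep = ret = None
        if ev["arrival"] is not None and arrival_lats:
            bdep = ph.detect_breeding_departure(whole, ev["arrival"], arrival_lats)
            if bdep is not None and poly is not None:
                ret = ph.detect_return_north(whole, poly, bdep)
        rec = ph.summarize_phenology(
            t, whole, migrant, dmax, ev["start"], ev["arrival"], bdep, ret
        )
        records.append(rec)

    ph.records_to_frame(records).to_csv(run_dir / "phenology.csv", index=False)
    cohort = ph.cohort_summary(records)
    (run_dir / "phenology_cohort.json").write_text(json.dumps(cohort, indent=2, default=str))

    # per-animal metrics + pooled TSA on segments
    metric_rows = []
    grid = None
    for t in filtered:
        if t.animal_id in cfg.tsa_exclude_ids or t.animal_id not in regularized:
            continue
        whole, segs = regularized[t.animal_id]
        rec = next((r for r in records if r.animal_id == t.animal_id), None)
        sm = step_metrics(segs)
        sm.insert(0, "id", t.animal_id)
        metric_rows.append(sm)
        if len(segs.data):
            phases = dv.assign_phase(
                list(segs.data["timestamp"]),
                rec.start_migration_date if rec else None,
                rec.arrival_breeding_date if rec else None,
                rec.departure_breeding_date if rec else None,
                rec.return_north_date if rec else None,
            )
            grid = accumulate_tsa(segs, np.array(phases), cell_km=cfg.cell_km, grid=grid)
    if metric_rows:
        pd.concat(metric_rows, ignore_index=True).to_csv(run_dir / "step_metrics.csv", index=False)
    if grid is not None:
        grid.to_frame().to_csv(run_dir / "tsa_grid.csv", index=False)
        tsa_summary(grid).to_csv(run_dir / "tsa_summary.csv", index=False)

    if cfg.fit_persistence:
        series = fit_move_persistence([regularized[a][1] for a in regularized])
        pd.concat(
            [s.data.assign(id=s.animal_id) for s in series], ignore_index=True
        ).to_csv(run_dir / "move_persistence.csv", index=False)

    if single_dives:
        all_dives = []
        for aid, dd in single_dives.items():
            rec = next((r for r in records if r.animal_id == aid), None)
            dd = dv.assign_dive_phases(
                dd,
                rec.start_migration_date if rec else None,
                rec.arrival_breeding_date if rec else None,
                rec.departure_breeding_date if rec else None,
                rec.return_north_date if rec else None,
            )
            all_dives += dd
        dv.phase_dive_summary(all_dives).to_csv(run_dir / "dive_summary.csv", index=False)

    manifest = {
        p.name: _sha256(p) for p in sorted(run_dir.iterdir()) if p.is_file() and p.name != "MANIFEST.json"
    }
    (run_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(run_dir, records, cohort, regularized, foraging_poly=poly)


def run_synthetic(cfg: PipelineConfig, sim: SimConfig) -> PipelineResult:
    """Generate a synthetic cohort and push it through the full pipeline."""
    tracks, truths = simulate_cohort(sim)
    dives = {}
    for th in truths:
        if th.is_migrant:
            dd, _ = simulate_dives(th, sim)
            dives[th.animal_id] = dd
    res = run_pipeline(cfg, tracks, single_dives=dives)
    res.truths = truths  # type: ignore[attr-defined]
    return res
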