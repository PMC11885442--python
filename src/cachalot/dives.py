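"""Binned dive summaries from depth-recording satellite tags.

SPLASH-style tags aggregate dives into 6-h histograms (counts per depth bin
and per duration bin, plus percent time-at-depth, TAD) and additionally
transmit a random selection of single dives with exact depth, duration and
time stamp. Two on-board configurations are supported, matching the two
programming setups used on sperm whales:

* config A — 14 depth bins with limits at 2, 4, 10, 20, 40, 60, 80, 100,
  150, 200, 250, 300, 350, >350 m and 14 duration bins with limits at
  6..30 min in 2-min steps, >30; dives shallower than 2 m and shorter than
  1 min ignored;
* config B — 10 depth bins with limits at 50, 100, 200, 300, 500, 700,
  1000, 1500, 2000, >2000 m and 7 duration bins with limits at 10, 20, 30,
  50, 60, 80, >80 min; dives shallower than 50 m and shorter than 5 min
  ignored.

Bins are half-open, lower-edge inclusive. The ignore rule is the logical
AND of the two conditions as worded on the tag datasheets; an OR variant is
available through ``ignore_rule`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DiveBinConfig:
    label: str
    depth_bin_edges_m: tuple[float, ...]  # interior limits; first bin starts at 0, last open
    duration_bin_edges_min: tuple[float, ...]
    ignore_below_depth_m: float
    ignore_below_duration_min: float
    ignore_rule: str = "and"  # "and" | "or"

    def __post_init__(self):
        for edges in (self.depth_bin_edges_m, self.duration_bin_edges_min):
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError("bin edges must be strictly increasing")
        if self.ignore_rule not in ("and", "or"):
            raise ValueError("ignore_rule must be 'and' or 'or'")

    @property
    def n_depth_bins(self) -> int:
        return len(self.depth_bin_edges_m) + 1

    @property
    def n_duration_bins(self) -> int:
        return len(self.duration_bin_edges_min) + 1

    def depth_bin_label(self, k: int) -> str:
        e = (0.0, *self.depth_bin_edges_m)
        return f">{e[-1]:g} m" if k == len(e) else f"{e[k]:g}-{e[k + 1]:g} m"

    def duration_bin_label(self, k: int) -> str:
        e = (0.0, *self.duration_bin_edges_min)
        return f">{e[-1]:g} min" if k == len(e) else f"{e[k]:g}-{e[k + 1]:g} min"


CONFIG_A = DiveBinConfig(
    label="A",
    depth_bin_edges_m=(2, 4, 10, 20, 40, 60, 80, 100, 150, 200, 250, 300, 350),
    duration_bin_edges_min=(6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30),
    ignore_below_depth_m=2.0,
    ignore_below_duration_min=1.0,
)

CONFIG_B = DiveBinConfig(
    label="B",
    depth_bin_edges_m=(50, 100, 200, 300, 500, 700, 1000, 1500, 2000),
    duration_bin_edges_min=(10, 20, 30, 50, 60, 80),
    ignore_below_depth_m=50.0,
    ignore_below_duration_min=5.0,
)


@dataclass(frozen=True)
class SingleDive:
    animal_id: str
    timestamp: pd.Timestamp
    max_depth_m: float
    duration_min: float
    phase: str = "unknown"


@dataclass
class DiveHistogram:
    animal_id: str
    period_start: pd.Timestamp  # aligned to 00/06/12/18 GMT
    depth_counts: np.ndarray
    duration_counts: np.ndarray
    tad_percent: np.ndarray | None = None
    phase: str = "unknown"


PHASES = ("foraging", "N-S", "breeding", "S-N")


def bin_dive(depth_m: float, duration_min: float, cfg: DiveBinConfig) -> tuple[int, int] | None:
    """Map one dive to (depth_bin, duration_bin), or None when ignored.

    Binning is half-open with the lower edge inclusive, so a 50-m dive
    under config B falls in the 50-100 m bin.
    """
    if depth_m < 0 or duration_min < 0:
        raise ValueError(f"negative depth or duration: ({depth_m}, {duration_min})")
    shallow = depth_m < cfg.ignore_below_depth_m
    short = duration_min < cfg.ignore_below_duration_min
    ignored = (shallow and short) if cfg.ignore_rule == "and" else (shallow or short)
    if ignored:
        return None
    kd = int(np.searchsorted(cfg.depth_bin_edges_m, depth_m, side="right"))
    kt = int(np.searchsorted(cfg.duration_bin_edges_min, duration_min, side="right"))
    return kd, kt


def build_histograms(dives: Sequence[SingleDive], cfg: DiveBinConfig) -> list[DiveHistogram]:
    """Aggregate a complete dive record into 6-h histograms.

    TAD is computed as the percentage of the 6-h period spent within each
    depth bin, attributing each dive's duration to its depth bin and the
    remainder of the period to the shallowest bin.
    """
    by_period: dict[tuple[str, pd.Timestamp], list[SingleDive]] = {}
    for d in dives:
        p0 = d.timestamp.floor("6h")
        by_period.setdefault((d.animal_id, p0), []).append(d)
    out = []
    for (aid, p0), group in sorted(by_period.items()):
        dc = np.zeros(cfg.n_depth_bins, dtype=int)
        tc = np.zeros(cfg.n_duration_bins, dtype=int)
        tad_min = np.zeros(cfg.n_depth_bins)
        for d in group:
            b = bin_dive(d.max_depth_m, d.duration_min, cfg)
            if b is None:
                continue
            dc[b[0]] += 1
            tc[b[1]] += 1
            tad_min[b[0]] += d.duration_min
        total = 360.0
        tad_min[0] += max(total - tad_min.sum(), 0.0)
        out.append(
            DiveHistogram(aid, p0, dc, tc, tad_percent=100.0 * tad_min / total,
                          phase=group[0].phase)
        )
    return out


def assign_phase(
    timestamps: Sequence[pd.Timestamp],
    start: date | None,
    arrival: date | None,
    breeding_departure: date | None,
    return_north: date | None,
) -> list[str]:
    """Label timestamps with the migration phase of their date.

    Boundaries are closed on the left: an item dated on the arrival date
    belongs to the breeding phase. An animal lacking a later event keeps
    the last resolved phase until the end of its record.
    """
    bounds = [
        ("foraging", start),
        ("N-S", arrival),
        ("breeding", breeding_departure),
        ("S-N", return_north),
        ("foraging", None),
    ]
    out = []
    for ts in timestamps:
        d = pd.Timestamp(ts).date()
        label = "foraging"
        if start is None:
            out.append("foraging" if arrival is None else "unknown")
            continue
        for phase, edge in bounds:
            if edge is None or d < edge:
                label = phase
                break
        else:
            label = "foraging"
        out.append(label)
    return out


def assign_dive_phases(dives: Sequence[SingleDive], start, arrival, breeding_departure, return_north) -> list[SingleDive]:
    phases = assign_phase([d.timestamp for d in dives], start, arrival, breeding_departure, return_north)
    return [
        SingleDive(d.animal_id, d.timestamp, d.max_depth_m, d.duration_min, ph)
        for d, ph in zip(dives, phases)
    ]


def phase_dive_summary(dives: Sequence[SingleDive]) -> pd.DataFrame:
    """Per-phase mean +- SD of maximum depth and duration.

    Also reports the deepest and longest dive with their phase; phases with
    no dives are omitted.
    """
    if not dives:
        return pd.DataFrame(columns=["phase", "n", "mean_depth_m", "sd_depth_m",
                                     "mean_duration_min", "sd_duration_min"])
    df = pd.DataFrame(
        {
            "phase": [d.phase for d in dives],
            "depth": [d.max_depth_m for d in dives],
            "dur": [d.duration_min for d in dives],
        }
    )
    rows = []
    for phase in [p for p in (*PHASES, "unknown") if p in set(df["phase"])]:
        g = df[df["phase"] == phase]
        rows.append(
            {
                "phase": phase,
                "n": len(g),
                "mean_depth_m": float(g["depth"].mean()),
                "sd_depth_m": float(g["depth"].std(ddof=1)) if len(g) > 1 else np.nan,
                "mean_duration_min": float(g["dur"].mean()),
                "sd_duration_min": float(g["dur"].std(ddof=1)) if len(g) > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    deepest = df.loc[df["depth"].idxmax()]
    longest = df.loc[df["dur"].idxmax()]
    out.attrs["deepest"] = {"depth_m": float(deepest["depth"]), "duration_min": float(deepest["dur"]), "phase": str(deepest["phase"])}
    out.attrs["longest"] = {"depth_m": float(longest["depth"]), "duration_min": float(longest["dur"]), "phase": str(longest["phase"])}
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_single_dives(path, id_col="DeployID", time_col="Date",
                      depth_col="Depth", dur_col="Duration") -> list[SingleDive]:
    """Read a single-dive table (one row per transmitted random dive)."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for col in (id_col, time_col, depth_col, dur_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    ts = pd.to_datetime(df[time_col], utc=True).dt.tz_localize(None)
    return [
        SingleDive(str(i), t, float(z), float(u))
        for i, t, z, u in zip(df[id_col], ts, df[depth_col], df[dur_col])
    ]


def write_single_dives(dives: Sequence[SingleDive], path) -> None:
    pd.DataFrame(
        {
            "DeployID": [d.animal_id for d in dives],
            "Date": [d.timestamp.strftime("%Y-%m-%dT%H:%M:%S") for d in dives],
            "Depth": [d.max_depth_m for d in dives],
            "Duration": [d.duration_min for d in dives],
        }
    ).to_csv(path, index=False)


def histograms_to_frame(histos: Sequence[DiveHistogram], cfg: DiveBinConfig) -> pd.DataFrame:
    rows = []
    for h in histos:
        row = {"DeployID": h.animal_id, "PeriodStart": h.period_start, "phase": h.phase}
        for k in range(cfg.n_depth_bins):
            row[f"depth_bin_{k}"] = int(h.depth_counts[k])
        for k in range(cfg.n_duration_bins):
            row[f"dur_bin_{k}"] = int(h.duration_counts[k])
        if h.tad_percent is not None:
            for k in range(cfg.n_depth_bins):
                row[f"tad_{k}"] = round(float(h.tad_percent[k]), 2)
        rows.append(row)
    return pd.DataFrame(rows)
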