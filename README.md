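# cachalot

Breeding-migration analytics for satellite-tagged adult male sperm whales
(*Physeter macrocephalus*).

Adult males feed at high latitudes (69–79°N in the Northeast Atlantic
Arctic) and travel to breeding grounds south of 45°N, where females and
juveniles live in social groups. Argos tags on these whales deliver
irregular, error-prone surface positions — surfacing-driven fix times,
location classes from 3 (best) to B (worst, ~10 km), multi-day
transmission gaps — from which the questions of interest must be squeezed:
*when* does a male leave the feeding grounds, *how fast* and *how far*
does he travel, *how long* does he stay in the south, and *when* does he
come back?

`cachalot` implements that full analysis chain as a tested, reusable
library:

1. **Track I/O and cleaning** (`track_io`) — Wildlife-Computers-style
   location tables; class-Z removal; duplicate timestamps nudged +1 s.
2. **SDA prefilter** (`prefilter`) — speed/distance/angle plausibility
   filter (5 m s⁻¹ bound; 15°/25° spikes at 2,500/5,000 m).
3. **State-space regularization** (`ssm`) — a continuous-time random walk
   `dX = σ dW` observed with class-dependent isotropic Gaussian error,
   fitted by exact maximum likelihood (Kalman filter over irregular steps
   in a local azimuthal-equidistant plane) and smoothed (RTS) onto a
   regular 2-h grid; one *whole-track* dataset that bridges gaps and one
   *segments-only* dataset (split at gaps > 72 h, ≥ 4 d long, ≥ 1 position
   per day) for behavioural metrics.
4. **Movement metrics** (`metrics`) — 2-h speeds, great-circle distances
   and bearings, and the move-persistence index γₜ ∈ (0, 1): the expected
   displacement vector at step *t* is γₜ times the previous one plus
   isotropic noise, with logit(γₜ) following a random walk whose variance
   is pooled across animals (Laplace-approximated marginal likelihood).
5. **Time-spent-in-area** (`tsa`) — hours apportioned to 50 × 50 km
   equal-area cells by exact line clipping (time is conserved per segment
   to 1e-9).
6. **Migration phenology** (`phenology`) — the core detector: migrant
   classification (≥ 1,000 km from tagging), a 100% minimum-convex-polygon
   foraging area from non-migrant tracks (one fix per 2 d), departure =
   definitive polygon exit, arrival = first decelerating position south of
   45°N (loess span 0.2 on the 2-h speed series), breeding departure =
   first crossing of the cohort-mean arrival latitude, return = first
   polygon re-entry, and whole-day leg durations.
7. **Dive summaries** (`dives`) — both 6-h binned tag configurations
   (14 depth × 14 duration bins, ignore < 2 m ∧ < 1 min; 10 × 7 bins,
   ignore < 50 m ∧ < 5 min), phase assignment, per-phase depth/duration
   statistics.
8. **Synthetic data** (`synth`) — a generator producing Argos-like tracks
   and dive records with known ground truth (multi-phase movement, class-
   dependent noise, transmission gaps), so every stage is testable without
   any tag data.
9. **Pipeline + CLI** (`pipeline`, `cachalot` console script) —
   end-to-end runs with plain-CSV stage outputs and a hashed MANIFEST.

## Worked example

```python
from cachalot import (SimConfig, simulate_track, clean_track, sda_filter, fit_ssm,
                      predict_regular, segment_track, classify_migrant, step_metrics)

cfg = SimConfig(seed=7)
track, truth = simulate_track(cfg, "demo-whale", migrant=True)
print(f"simulated fixes: {len(track)}")
cleaned = clean_track(track)
filtered, removed = sda_filter(cleaned)
print(f"after cleaning/SDA filter: {len(filtered)} fixes kept, {len(removed)} removed")
fit = fit_ssm(filtered)
print(f"fitted process scale: sigma = {fit.sigma:.2f} km/sqrt(h)")
whole = predict_regular(filtered, fit)
segs = predict_regular(filtered, fit, windows=segment_track(filtered),
                       dataset_kind="segments_only")
print(f"regularized positions: {len(whole)} (whole track), {len(segs)} (segments)")
flag, dmax = classify_migrant(cleaned)
print(f"migrant: {flag} (max displacement {dmax:,.0f} km)")
sm = step_metrics(whole)
print(f"cumulative distance: {sm['cumulative_distance_km'].iloc[-1]:,.0f} km")
print(f"true event dates: departure {truth.departure_date}, arrival {truth.arrival_date}, "
      f"breeding departure {truth.breeding_departure_date}, return {truth.return_date}")
```

which prints:

```
simulated fixes: 3128
after cleaning/SDA filter: 2088 fixes kept, 984 removed
fitted process scale: sigma = 5.40 km/sqrt(h)
regularized positions: 2589 (whole track), 2417 (segments)
migrant: True (max displacement 4,210 km)
cumulative distance: 15,877 km
true event dates: departure 2022-07-19, arrival 2022-08-20, breeding departure 2022-10-29, return 2022-12-03
```

Reading: the tag produced 3,128 raw fixes; the SDA filter discarded 984
implausible ones (mostly class-B spikes); the fitted random-walk scale is
5.4 km per √hour; the whale is classified a migrant (4,210 km maximum
displacement from tagging) and covered ~15,900 km over its full cycle —
the same order as real complete migrations (16,000–17,700 km). Running
the phenology detectors on the regularized track recovers the generator's
event dates to within ±1–2 days (see `tests/test_acceptance.py`).

The same chain is available from the shell:

```bash
cachalot synth --seed 7 --n-migrants 2 --n-residents 3 --out fixtures/
cachalot prefilter --vmax 5 --in fixtures/locations.csv --out filtered.csv --removed removed.csv
cachalot ssm --in filtered.csv --out regular.csv --dataset segments_only
```

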