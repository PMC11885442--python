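# Methods

This note documents the models, detectors and numerical choices behind
`cachalot`, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Data model and cleaning

All timestamps are GMT throughout; satellite tags are programmed in GMT
and no timezone inference is ever attempted. A track is one animal's
time-ordered Argos fixes with location classes {3, 2, 1, 0, A, B, Z}.
Cleaning removes class-Z fixes first (failed localizations carry no usable
position), then enforces strictly increasing timestamps by shifting any
tied fix forward 1 s, repeatedly — so three fixes at the same instant end
up +1 s and +2 s apart. The order (Z removal before duplicate adjustment)
is a design choice; it only matters when a Z fix sits inside a tie run,
and either order yields a valid strictly-monotone track.

Input tables default to the Wildlife Computers "-Locations.csv" layout
(DeployID / Date / Latitude / Longitude / Quality); the dialect is a
config object because tag vendors do not share a schema. Unparseable rows
are counted and reported in a warning, never silently dropped.

## SDA prefilter

The speed/distance/angle filter removes fixes that imply impossible
movement before any model sees the data:

* **speed rule** — an interior fix is implausible when its minimum implied
  straight-line speed to the retained neighbours exceeds `vmax`
  (default 5 m s⁻¹, roughly twice a sustained sperm whale travel speed);
* **spike rule** — a fix forming an out-and-back excursion is implausible
  when the turning angle is below 15° with both legs over 2,500 m, or
  below 25° with both legs over 5,000 m (the classical defaults of this
  filter family).

Pairs separated by more than 24 h (configurable) are exempt from the speed
test: over a multi-day gap the straight-line bound carries no information.
Each pass removes the single worst offender (highest implied speed, then
smallest angle) and re-evaluates, which makes removal order deterministic;
iteration runs to a fixed point, and first/last fixes are always kept. A
final pass enforces the pairwise speed bound for retained non-gap pairs (a
rare residual case of the min-speed rule). With a B-heavy class mix the
filter typically removes 20–35 % of fixes, almost all tagged `spike`; that
is expected behaviour at ~10 km class-B noise, not data loss — the state-
space model would otherwise have to absorb those excursions.

## State-space regularization

The movement model is the simplest continuous-time process consistent with
the data: 2-D Brownian motion with scale σ (km √h⁻¹), observed at
irregular surfacing times with isotropic Gaussian error whose SD depends
on the Argos class (defaults 0.25 / 0.5 / 1.5 / 5 / 5 / 10 km for classes
3 / 2 / 1 / 0 / A / B — literature-typical values, exposed in config
because Argos does not publish per-class SDs).

All linear algebra runs in a **local azimuthal-equidistant plane** centred
on the track centroid: a random walk written in lat/lon degrees is badly
anisotropic at 70–79°N (a longitude degree is ~3× shorter than a latitude
degree). Because the error model is isotropic, the two planar coordinates
decouple into independent scalar Kalman recursions sharing σ; the exact
likelihood is maximized over log σ by bounded scalar optimization. The
initial state is the first observation with a 1,000 km prior SD — wide
enough to be effectively diffuse, finite so the likelihood stays proper
and testable against a dense joint-Gaussian oracle (agreement to 1e-6 and
better is asserted in the tests).

Prediction uses the RTS smoother on the union of observation and 2-h grid
nodes. Two datasets are produced:

* **whole-track** — one pass over the full record; predictions bridge
  transmission gaps with honestly inflated uncertainty. Used for
  cumulative distances and migration timing, where a gap must not hide an
  event.
* **segments-only** — independent passes over well-sampled windows. The
  track is cut at gaps > 72 h *and* wherever a gap leaves a whole calendar
  date without a fix; windows shorter than 4 d are discarded. (An earlier
  reading that discarded any window containing an empty date proved
  degenerate — one missing day would delete a five-month segment — so the
  daily-coverage requirement is enforced by splitting, which preserves the
  invariant that every kept segment has at least one position per spanned
  day.) Used for speeds and behavioural indices, where interpolating
  across a gap would fabricate slow movement.

## Movement metrics

Speed is the straight-line displacement between consecutive 2-h modelled
positions divided by 2 h, on segments only. It systematically understates
true speed — whales do not travel in straight lines between modelled
positions, and they move in three dimensions — and no correction is
attempted. Cumulative distance runs over the whole track, bridging
segment joins linearly (again an underestimate, flagged as such).
Bearings are initial great-circle azimuths, degrees clockwise from north;
all great-circle arithmetic uses the haversine on a 6,371.0 km sphere.

**Move persistence** γₜ ∈ (0, 1) captures joint autocorrelation in speed
and direction: E[dₜ] = γₜ dₜ₋₁ with isotropic Gaussian innovations, and
logit(γₜ) follows a Gaussian random walk. Estimation is by
Laplace-approximated marginal likelihood: the inner mode over the logit
series is found by damped Newton steps (the joint Hessian is tridiagonal —
diagonal Gauss-Newton data term plus the random-walk prior — so each step
is a banded solve), and the two variance parameters are optimized by
Nelder-Mead on the Laplace objective. When several animals are fitted
jointly both variances are pooled, making γ comparable between
individuals; each segment carries its own logit chain (the random walk
restarts across gaps). Verified behaviour: γ ≈ 0.99 for constant-velocity
motion, ≈ 0 for i.i.d. jitter, and monotone in the directional
correlation of a simulated correlated walk.

## Time spent in area

TSA accumulates hours on a 50 × 50 km grid in a Lambert azimuthal
equal-area plane centred on the data centroid (equal-area, so cells stay
metrically 50 km from the Arctic to the tropics). Each 2-h step's
duration is apportioned to cells in proportion to the straight sub-segment
length inside each cell, computed by exact parametric line clipping
against the grid lines; zero-length steps assign their whole 2 h to the
containing cell. This conserves time per segment to 1e-9 relative (an
asserted invariant) and is insensitive to positions that sit exactly on a
cell border. Known analyst practice of excluding individual outlier
animals is supported through an exclusion list in the pipeline config, not
hard-coded.

## Migration phenology

* **Migrant classification**: maximum great-circle displacement from the
  tagging location, threshold 1,000 km, inclusive (≥). The observed
  distribution of maxima is strongly bimodal around this value, so the
  threshold is not delicate.
* **Foraging polygon**: 100% minimum convex polygon over non-migrant
  locations subsampled to one fix per two days (reducing autocorrelation
  so no single sampling burst shapes the hull). Hull and area are
  computed in the equal-area plane; containment is closed (boundary points
  are inside). Collinear or near-degenerate point sets raise a typed
  error.
* **Departure**: the last exit from the foraging polygon not followed by a
  re-entry — unless that re-entry happens after the animal has been south
  of 45°N, in which case it is the S-N return and does not disqualify the
  exit. Departure runs on the whole-track dataset so a transmission gap
  cannot hide the exit.
* **Arrival**: the first 2-h position south of 45°N (the classical
  delineation of North Atlantic breeding latitudes) at which the animal is
  decelerating. Deceleration is the sign of the first derivative (central
  differences) of a loess fit to the segments-only speed series — tricube
  weights, span 0.2, local quadratic, matching the R `loess` defaults for
  degree. The loess is hand-implemented because the available Python
  lowess is local-linear only; it is verified to reproduce a global
  quadratic exactly.
* **Breeding departure**: first post-arrival position north of the mean
  arrival latitude. The cohort mean is the default (a pooled definition
  of the breeding-area boundary); a per-individual variant is available by
  passing a single-element latitude list.
* **Return**: first re-entry into the foraging polygon after breeding
  departure.

Durations are whole-day differences of event dates (GMT), so
N-S + breeding + S-N equals the whole-cycle duration exactly whenever all
four dates exist. Cohort summaries use the sample SD (n − 1) rounded to
integer days; the departure-date span is computed within the calendar year
(day-of-year), since departures are asynchronous across years.

## Dive summaries

Both tag programming configurations are first-class config objects; bins
are half-open with the lower edge inclusive (a 50 m dive under the
deep-water configuration falls in 50–100 m). The ignore rule — "shallower
than X *and* shorter than Y" — is implemented as the logical AND per its
wording; an OR variant is exposed as `ignore_rule="or"` because the
sentence admits both readings. Histograms aggregate dives into 6-h
periods aligned to 00/06/12/18 GMT; TAD attributes each dive's duration to
its depth bin and the period remainder to the shallowest bin, summing to
100 ± rounding. Phase assignment is closed-left on event dates (a dive on
the arrival date is a breeding-phase dive); an animal missing a later
event keeps its last resolved phase to the end of the record.

## Synthetic-data generator

The generator is the package's study-conditions module: its defaults are
the conditions everything is tested under, chosen once from what is known
about this system and not revisited.

* **Cohort**: foraging home-range centres strung along a quasi-linear
  shelf-edge band (69.5–73°N), with small cross-shelf jitter — tagging
  sites on a continental shelf edge form a band, not a 2-D cloud, and this
  is also why a moderate number of residents (the default recovery
  experiments use 14, against 20 migrants) suffices for their polygon to
  cover the migrants' foraging ranges.
* **Foraging**: heading-persistent bouts at 2.0 km h⁻¹ with drift toward
  the home-range centre (48-h relaxation), giving excursions of roughly
  ±100 km.
* **N-S transit**: 4.7 km h⁻¹ toward a breeding entry point near 42.5°N
  drawn ~30–40° of longitude to the south-west, with AR(1) heading noise;
  the final ~400 km approach tapers linearly down to the breeding speed,
  so the behavioural arrival — the first sustained deceleration south of
  45°N, which is exactly what the detector estimates — is well defined on
  the true path.
* **Breeding**: correlated roaming at 3.4 km h⁻¹ weakly attracted to a
  centre near 36°N, producing the wide, wandering southern range.
* **S-N transit**: 4.4 km h⁻¹ back toward the foraging centre; the truth
  return is the first approach within 170 km of it (about the radius of a
  resident's polygon).
* **Observation**: gamma inter-fix intervals (mean 1.5 h), a B-heavy
  class mix (B 48 %, A 25 %, 0 10 %, 1 7 %, 2 5 %, 3 3 %, Z 2 %) with the
  same class SDs the SSM assumes, occasional exact-duplicate timestamps,
  and a gap process of Poisson starts (one per ~8 d) whose durations mix
  short drop-outs (log-normal, median 8 h) with rare multi-day outages
  (15 %, uniform 80–140 h) — so the >72 h segmentation rule is genuinely
  exercised.
* **Dives**: per-phase clamped normals — foraging 343 ± 283 m / 30 ± 10
  min, transits 750 ± 300 m / 45 ± 12 min, breeding 849 ± 444 m /
  51 ± 15 min — with 6-h histograms built by exact binning of the same
  dives, so summary/histogram consistency is a testable identity.

**Ground truth for event recovery.** The generator's arrival truth is the
first decelerating position south of 45°N on the true path, and its
departure/return truths are the true path's definitive exit from and first
re-entry into the (analysis-supplied) foraging polygon — i.e. the
noise-free counterparts of what the detectors estimate. Recovery tests
therefore measure what the estimation chain adds in error (Argos noise,
gaps, smoothing, the 2-h grid, date rounding), not a mismatch between two
different event definitions. At default noise, 20 seeded migrants give
100 % classification accuracy, ≥ 90 % of departures and arrivals within
±2 d and returns within ±3 d; the occasional miss is an arrival falling
inside a multi-day transmission outage — which is also how missing
arrivals arise in real deployments.

**What the generator does not emulate**: bathymetry, currents, sea ice,
coastlines (tracks may cross land), behaviourally mechanistic diving,
tag-failure physics (battery decay, fouling), or inhomogeneous Argos
coverage with latitude. Passing the recovery tests therefore shows that
the estimation chain is correct under the stated statistical structure —
not that real tracks satisfy that structure.

## Problem sizes and determinism

The default test and reproduction runs use a cohort of 20 migrants + 14
residents with ~200–290-day tracks at ~16 fixes/day (≈ 3,000 fixes per
animal), which the full pipeline processes in about a minute; these sizes
were chosen as the smallest at which cohort-level rates (90 % recovery
thresholds) are meaningful. Every random draw flows from a single
`numpy` `default_rng` seed; the pipeline writes a MANIFEST of SHA-256
content hashes, and a rerun with the same inputs and seed is
byte-identical.

## Known limitations

* The Brownian-motion movement model has no velocity persistence; during
  fast directed transit the smoother slightly over-smooths corners. A
  correlated-velocity model would sharpen this at the cost of two more
  parameters; the simple random walk is the reference behaviour here.
* Speeds and distances are 2-D chord underestimates (acknowledged above).
* The arrival detector inherits the loess span: with span 0.2 on a
  multi-month series the smoothing window is weeks wide, and the detected
  arrival can shift by a day or two relative to the underlying behavioural
  change; the detector is only day-accurate when deceleration is underway
  near the 45°N crossing.
* Cohort-mean arrival latitude makes the breeding-departure date of each
  animal depend on which other animals are in the analysis; the
  per-individual variant avoids this at the cost of comparability.
* GAMM/quantile-regression modelling of metrics against days-to-departure,
  and mixed-model comparisons of dive metrics between phases, are outside
  this package's scope: they are ordinary applications of existing
  statistical packages on the CSV outputs produced here.
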