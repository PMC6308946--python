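# Methods

## The model

Each meteorological danger index *i* ∈ {A, B, C, D} carries a fixed
saturation score *K_i* ∈ {20, 20, 10, 40} and a small step-interval sample
set {(x, y)}: variable values (interval midpoints) paired with the step
scores of the operational standard. The smoothed scoring function is the
two-parameter logistic curve

    Y'_i(x) = K_i / (1 + exp(alpha_i + beta_i x)),

with *K_i* fixed, not estimated. The exponent is written exactly as
`alpha + beta·x`, so `beta` is negative for the increasing curves
(temperature, wind) and positive for the decreasing ones (humidity, rain).
Relative humidity is a fraction in [0, 1] everywhere inside the package;
its scoring curve's coefficients are only meaningful on that scale, and the
humidity functions reject inputs above 1 to catch percent/fraction mix-ups.

### Fitting

Every sample set pins both endpoints — a score of exactly 0 at one end and
exactly *K* at the other. Those endpoints have no finite logit, which
rules out plain logit linearisation, and they dominate the behaviour of the
fit. The default estimator treats the score fraction *y/K* as a
binomial-family response and maximises the quasi-likelihood by iteratively
reweighted least squares (IRLS): endpoint observations are ordinary data on
this route, the optimum is unique, and the resulting curves for all four
built-in sets agree with their widely printed coefficients to all four
published decimals. An unweighted Gaussian nonlinear least-squares route
(`method="nls"`, Levenberg–Marquardt) is provided for comparison; it
minimises squared error on the score scale and yields slightly different
coefficients because it weights mid-curve points more heavily relative to
the endpoints.

IRLS details: starting values come from a linear regression on the logit of
the score fraction clipped into [0.01, 0.99]; iteration stops when the
coefficient step and the deviance change both fall below 1e−12, with a hard
cap of 100 iterations (non-convergence raises a fitting error). A set with
all scores equal is rejected as degenerate. Standard errors use the Fisher
information with a Pearson-χ²/df dispersion (quasi-binomial), since the
score fractions are not true binomial counts.

Goodness of fit is reported on the score scale: R² = 1 − SSres/SStot with
SStot about the mean score. With the default fitter the four built-in sets
give R² = 0.9771 (temperature), 0.9771 (humidity), 0.9656 (rain) and
0.9691 (wind). Published summaries of these fits attribute the two
smallest values the other way around between the rain and wind indices;
the package reports what it computes from its own fitted curves, and its
acceptance tooling compares the sorted values so that nothing depends on
the attribution.

A useful identity: the humidity sample set is the affine image of the
temperature set under x → 0.80 − 0.02x. Both fitting routes are
equivariant under affine maps of x, so the two fits must have identical R²
and betas related by the factor −1/0.02. The test suite uses this as a
fitter oracle that is independent of any published coefficient.

### The component indices

* **Y'_A** (temperature) and **Y'_D** (wind): the fitted logistic curves
  evaluated at the daily maximum air temperature (°C) and daily maximum
  wind speed (m/s). Strictly monotone, outputs strictly inside (0, K).
  Wind enters in m/s directly — the wind sample set's abscissae are
  wind-class midpoint speeds in m/s, and the smoothing replaces the class
  steps, so no Beaufort-class conversion is applied.
* **Y'_B** (humidity): the logistic curve at the daily minimum relative
  humidity (fraction); strictly decreasing.
* **Y'_C** (precipitation): for a daily amount up to 10 mm, the logistic
  scoring of the amount plus a consecutive-day bonus `5·t`; above 10 mm the
  index collapses to `5·(t − 1)`. The result is clamped to [0, 50] — the
  upper cap is part of the standard; the lower clamp is this package's
  choice so the `5·(t − 1)` branch at `t = 0` cannot drive the composite
  negative.

  The counter `t` is genuinely ambiguous in the sources this equation
  derives from: the index is described as counting days *without*
  precipitation, the fitted abscissae behave as precipitation *amounts*,
  and `t` is elsewhere described as counting days *with* precipitation even
  though the `+5t` term increases fire danger. The package implements the
  printed arithmetic and makes the binding explicit: daily aggregation
  maintains both a dry-run and a wet-run counter, and
  `IndexEquations(c_run_counter=...)` selects which one feeds `t`. The
  default is `"dry"` — the count of consecutive rain-free days ending
  today — which makes the bonus grow through a dry spell and reset on rain,
  the behaviour consistent with the rest of the index. The ambiguity is
  deliberately surfaced in the API rather than silently resolved.
* **Y'_E1** (phenology): a calendar step — 0 outside the fire season, 15 in
  the fire season, 20 in the core fire season, all configurable. The
  default calendar (fire season 1 Mar–15 Jun and 15 Sep–30 Nov, core
  15 Mar–31 May) describes a northern temperate spring/autumn fire regime;
  no authoritative dates exist, so the calendar is a plain config object.
* **Y'_E2** (litter-layer soil moisture): 0 below 5 % humus-layer VWC,
  `4 − 80·VWC` from 5 % to 30 %, −20 at and above 30 %; continuous at both
  breakpoints. The humus-layer moisture proxy is the daily mean of the
  10 cm soil-moisture channel (configurable to the daily minimum); the
  40 cm channel is ingested and reported but never enters the grade.

### Composite and grade

The composite is the plain sum of the six components. The grade table is
stated in integer intervals with gaps between them (…≤25 | 26–50 | …), so
real-valued composites are rounded half-up to the nearest integer before
lookup; this keeps the printed integer thresholds verbatim and makes grade
a non-decreasing step function of the composite. 25.4 grades I, 25.5
grades II.

## Daily aggregation

Records arrive at a fixed cadence (10 min default, 144/day). Aggregation
is order-insensitive: records are sorted and de-duplicated on timestamp, so
re-sent or shuffled telemetry cannot change a summary. Day boundaries are
station-local midnight; timestamps are treated as station-local throughout.

Gap policy: on the day's cadence grid, missing runs of at most `max_gap`
minutes (default 30) are bridged — continuous channels by linear
interpolation in time, precipitation by zeros (absence of a report is
treated as no rain only across short gaps). Longer runs stay missing and
set the day's `gap_flag`; flagged days are still scored but carry a quality
marker into the assessment. Days below `min_coverage` (default 80 %) of
expected records raise a low-coverage error carrying the partial summary;
the series-level driver keeps such days but flags them.

A day is a *rain day* when its precipitation total reaches
`rain_day_threshold` (default 0.1 mm — the standard trace threshold; the
sources define no explicit cut). Dry-run and wet-run counters are updated
day by day; exactly one is positive on any day. A wholly missing calendar
day restarts both counters (conservative: a dry spell cannot be extended
through unobserved days).

## The synthetic station generator

The generator exists so the full pipeline is testable without field data.
It emulates, per 10-minute interval:

* **temperature** — season mean (12 °C) + diurnal sinusoid peaking at
  14:00 (amplitude 8 °C) + AR(1) noise (sd 1.5 °C, per-interval
  autocorrelation 0.95), with wet days 4 °C cooler (overcast conditions);
* **humidity** — base 0.45, anti-correlated with the temperature anomaly
  (−0.015/°C), elevated by 0.30 on wet days, AR(1) noise, clipped to [0, 1];
* **wind** — i.i.d. Weibull (shape 2, scale 3 m/s), the standard
  surface-wind family;
* **rain occurrence** — a daily two-state Markov chain
  (P(wet|wet) = 0.45, P(wet|dry) = 0.12, initialised from its stationary
  distribution), giving the clustered wet spells and multi-day dry runs the
  run counters need; each wet day's exponential total (mean 8 mm) falls in
  one random 2–6 h window;
* **soil** — a leaky bucket: the 10 cm channel gains 0.012 VWC per mm of
  rain and relaxes toward a dry floor (0.08) at 4 %/day, capped at 0.45, so
  it rises fast under rain and drains over weeks; the 40 cm channel relaxes
  toward the 10 cm value at 8 %/day, so brief showers barely reach it.

The defaults describe a 92-day temperate spring fire season. All
randomness flows from one seed through named substreams (temperature,
humidity, wind, rain, soil), so tests can vary one process while holding
the others fixed — the deep-soil test, for instance, compares two runs that
differ only in rain amounts.

What the generator does **not** emulate: seasonal trend within the
campaign, wind persistence and diurnal wind cycles, frontal structure
(rain, wind and pressure co-movement), snow, sensor drift or error, and the
one-record fencepost by which a real logger's 92-day campaign can total
13,247 rather than 92 × 144 = 13,248 frames. Consequently, passing tests
demonstrate that the pipeline arithmetic and its qualitative responses
(grades fall under sustained rain, rise through hot dry windy spells) are
correct — not that the index is skilful on real station data.

`recover_parameters` closes the loop with method-of-moments estimates of
the wet-day frequency and mean wet-day rain; the test suite checks them on
2,000 simulated days (at 60-minute cadence, which only coarsens the
intra-day rain placement, not the daily totals under test) against binomial
and 3-standard-error intervals.

## Telemetry

Stations in regions without cellular coverage report over a satellite
short-message service with a fixed 72-byte payload. The frame layout
(documented byte-by-byte in `firegrade/telemetry.py`) is this package's
own: magic/version header, 16-byte station id, 8-byte epoch timestamp, six
fixed-point channels (0.01 °C / 0.01 m/s / 0.01 mm steps; 10⁻⁴ steps for
the fractional channels), zero padding, CRC-16/CCITT. Round-trip error is
bounded by half a step per channel. The channel model is Bernoulli
per-frame delivery with a configured success probability — no latency,
ordering or protocol behaviour — and its delivery report carries the
sent/delivered counts and empirical rate. A campaign-sized run
(13,247 frames) lands inside the 99.9 % binomial interval of its configured
rate, mirroring the observed 98.6–99.9 % delivery of the satellite and
GPRS links such systems report.

## Problem sizes

The test suite and acceptance tooling run at desk scale by design: curve
fits on the 6–9-point sample sets (milliseconds), grade-behaviour checks on
one 92-day synthetic campaign, Monte-Carlo recovery on 2,000 synthetic days,
channel checks on 13,247 frames. These sizes keep every statistical
interval meaningful while the whole suite completes in seconds.

## Known limitations

* The step-interval *boundaries* of the original standard are not public —
  only interval midpoints — so the package cannot reproduce, or be compared
  against, the original stepwise scoring.
* The precipitation counter ambiguity (above) is configurable, not
  resolved.
* Grade skill on real data is untested here: no public station series with
  reference grades exists, and the synthetic generator is a statistical
  stand-in, not a climate model.
* The phenology calendar is a default, not a national table; operational
  use should configure region-specific dates.
* Aggregation assumes station-local timestamps; cross-zone portability is
  the caller's responsibility.
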