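# Methods

This note documents the models, definitions and numerical choices behind
`rtlsval`: what each validation statistic means, what the synthetic scenes
do and do not emulate, and where the design was genuinely open.

## Data model

A position stream is a sequence of 2D fixes `(tag_id, t, x, y)` in barn
coordinates: origin at the lower-left corner, x along the long axis, y
along the short axis, metres. Timestamps are ISO-8601 in files and seconds
since the session start internally. A `Session` carries the wall-clock
bounds, a free-form `period_label` used for stratification (e.g.
`pre_update`/`post_update` around a provider software update), and the
nominal sampling rate (default 1 Hz). Height (z) is stored only for anchor
and stationary-tag placements; streams are strictly 2D, matching how such
systems are analysed in practice.

On ingest, duplicate `(tag, timestamp)` rows keep the first occurrence and
the drop count is reported (`ParseReport`), so row counts always conserve.
Parsing is deterministic: a stable sort keeps equal-timestamp file order.

The `netluky_layout()` preset describes a 31 m × 12 m free-stall barn with
six perimeter anchors at 4 m height and ten stationary reference tags:
three on the feeding table at ~2 m (out of the animals' reach, the outer
two in the upper corners), three in the end-of-barn cubicle row (one in
the lower-left corner), two in the mid-barn cubicle area and two by the
mid-barn water troughs, at 1–1.5 m. The tag coordinates are **nominal** —
chosen to be consistent with the qualitative zone description and flagged
as such in the layout metadata — because the source installation is
documented only graphically.

## Reliability

`reliability = 100 · actual / expected`, with
`expected = ⌊session length in s⌋ · nominal rate`. The floor is a
deliberate convention (no rounding rule is standard); with 1 Hz sampling
it means a 600.9 s window expects 600 fixes. Fixes inserted by gap
interpolation are flagged synthetic and never count.

Interval statistics pool the differences between consecutive fixes
*within* each tag-session stream only — session boundaries never fabricate
gaps. The long-delay analysis takes the empirical `long_quantile` (default
0.99) of the pooled differences as a threshold and attributes the
differences above it to tags as percent shares (summing to 100 %). The
quantile is configurable because "the top 1 %" is a reporting choice, not
a property of the system.

## Precision

Precision is dispersion about the centroid, not accuracy against surveyed
coordinates (none exist in the intended use case): per observation period
the centroid is the component-wise mean of the period's fixes, and each
fix's error is its Euclidean distance to that centroid. The centroid is
computed from the same fixes it is compared against; the mild
self-centering bias (the centroid chases large outliers) is accepted
rather than corrected, since the figure is meant to mirror field practice.
Grouping is by calendar day of the session's local clock (`group_by="day"`)
or by whole session; thresholds default to 0.3 m and 2.0 m and are
overridable. Stratified summaries (`stratified_precision`) describe
period-label strata without inference; a stratum with no data is absent
from the output, never reported as zero.

Under isotropic Gaussian jitter with per-axis σ, centroid distances are
Rayleigh: mean σ√(π/2), tail P(d > r) = exp(−r²/2σ²). These closed forms
are the oracles for the statistical tests (e.g. σ = 0.1 m ⇒ mean
0.1253 m, 0.3 m exceedance 1.11 %).

## Proximity concordance

A fix is in proximity of a stationary tag when their distance is
*strictly* below the radius (default 2.0 m ≈ one cow body length); the
nearest such tag is assigned, ties to the lexicographically smallest id
for determinism. Episodes are maximal same-tag runs; for system streams,
interior gaps up to `max_gap` (default 2 s, matching the observed median
interval regime) are bridged.

The observer protocol is the reference. Each 15-s protocol record stands
for the interval it opens; observer episodes are maximal runs of
consecutive same-tag records, covering `[first t, last t + 15)`.

Classification is window-based. For every 15-s window the system's verdict
is the modal in-proximity tag among the window's fixes (no fix in
proximity → none; tied mode → none, conservative against the system under
test). An observer episode is **congruent (scenario 1)** only if every one
of its windows matches the observer tag — a single missed 15-s window is
an error, which is also how such errors are counted in field protocols.
Otherwise the modal verdict among the mismatched windows decides:
mostly-none → **scenario 2** (system missed), mostly another tag →
**scenario 4** (wrong identity), ties to 2. Windows where the observer
recorded no proximity but the system's verdict names a tag form
**scenario 3** (spurious) cases, one per maximal run; they have no
observer denominator and are tallied separately. Error durations count
mismatched windows at full window length, so the total error duration is
exactly the summed mismatched window time. Accuracy is the percent of
observer proximity episodes classified congruent.

An open point, resolved here: with sub-episode partial matches the
classification could alternatively use the episode-level modal verdict
(an episode mostly detected counting as congruent). The all-windows rule
was chosen because it keeps "congruent ⇔ zero error duration" exact and
makes error-duration bookkeeping conservative; the per-case window counts
are available on each `ConcordanceCase` for anyone wanting the other
reading.

## Rig test

Fixes are bucketed by `⌊t⌋`; a matched triple exists for every second in
which all three rig tags have at least one fix (first fix per tag per
second — multiple fixes in one second are rare at a 1 Hz nominal rate).
Outer→middle distances are summarised per pair (mean ± SD, range) and
pooled as the percent "meeting" the nominal 0.3 m spacing. Because
"meeting 0.30 m" is ambiguous, both readings are implemented behind the
`rule` flag: `deviation` (default) counts `|d − 0.3| ≤ tolerance`,
`absolute` counts `d ≤ tolerance`. Path reconstruction
(`export_track_polyline`) joins consecutive fixes in order with no gap
correction, as a GeoJSON LineString in barn metres.

## Trajectory cleaning

* `jump_filter(min_jump=2 m)` removes isolated spikes: fixes farther than
  `min_jump` from *both* temporal neighbours (endpoints: their single
  neighbour). Genuine fast traversals survive because consecutive fixes
  move together.
* `median_smooth(window=5)` is a centred per-coordinate running median;
  near the edges the window shrinks symmetrically (odd size, fix kept
  centred), which makes constant and monotone streams exact fixed points.
* `interpolate_gaps(max_gap)` inserts linearly interpolated fixes at the
  whole seconds strictly inside gaps no longer than `max_gap`; inserted
  fixes carry a synthetic flag and are excluded from reliability and from
  file export.

These are the simplest standard forms of the three repairs; order of
application is explicit (CLI `--ops` applies left to right) since
different orders give different results and no single order is canonical.
Kalman filtering is deliberately out of scope — it needs a motion model
this package does not presume.

## Synthetic scenes and the error model

Ground-truth motion is a random-waypoint walk: pick a zone (by weight), a
uniform point inside it (a margin off the walls), move straight at a
uniform speed from `speed_range` (default 0.3–1.0 m/s, a slow steady cow
pace), dwell 5–60 s, repeat; positions are sampled at every whole second.
The rig walk runs the same process for the middle tag and places the outer
tags exactly ±0.3 m along the stick axis (aligned with the walking
direction, heading frozen during dwells), so truth spacing is exact by
construction. `truth_from_waypoints` builds deterministic scripted tracks
for scenario tests.

Corruption (`corrupt_track`) applies, per truth second:

1. **Dropout**: emitted with probability
   `p(x, y) = max(floor, p_base · (1 − exp(−d/L)))`, `d` the distance to
   the nearest wall. Defaults `p_base = 0.95`, `L = 2 m`, `floor = 0.04`.
2. **Jitter**: isotropic Gaussian with
   `σ(x, y) = σ_base + σ_edge · max(0, 1 − d/L)` (defaults 0.04 m + 0.5 m
   edge inflation, giving ≈0.04–0.55 m between centre and corner).
3. **Jumps**: with probability `p_jump` (default 0.002) the fix is
   displaced by a uniformly oriented vector of magnitude U(2, 15) m — a
   single-sample reflection error; it displaces rather than
   replaces-and-holds.

Timestamps of emitted fixes are exactly the truth seconds: corruption
never invents time points. All randomness derives from
`(model.seed, tag_id)` so multi-tag scenes are independent yet
byte-reproducible. `return_labels=True` exposes the truth provenance
(detected mask, jump mask, truth coordinates) for filter and recovery
oracles.

The exponential-decay / linear-inflation forms are the simplest monotone
models of the observed wall-and-corner degradation; the field data state
no functional form. Known limitations of this emulation:

* With the preset's nominal coordinates the dropout model spans roughly
  24–91 % per-tag reliability. Real campaigns report wider spans (down to
  ~4 % for a corner tag behind gates and walls): a pure wall-distance
  decay cannot reproduce that ratio, because extreme outliers are driven
  by local obstructions the model does not represent.
* Dropout is i.i.d. per second, so gap lengths are geometric (this is
  asserted by a goodness-of-fit test). Real systems also show bursty
  outages (observed maxima of hundreds of seconds); the model does not
  generate those, so burst-robustness of downstream analyses is untested.
* The observer protocol is error-free by default (`miss_rate = 0`): the
  trained observer is the reference, as in field validation. Each
  simulated record carries the modal per-second proximity over its 15-s
  interval — the same aggregation the concordance windows use — so a
  noise-free system achieves exactly 100 % congruence; an
  instantaneous-sample observer would disagree with any window-aggregated
  system at zone crossings even without noise.
* No physical UWB channel modelling (multipath geometry, time-of-flight
  solvers); the taxonomy is phenomenological.

Consequently, passing tests demonstrate that the *analytics* are correct
and that the pipeline recovers known parameters under this error taxonomy;
they do not certify any particular hardware installation.

## Report assembly

`run_full_validation` executes the configured blocks with module defaults
and assembles a pydantic `ValidationReport`; numbers are bit-identical to
the modules' outputs (assembly never re-rounds). Rounding to presentation
precision (percent and seconds to 2 decimals, metres to 3) happens only in
`render_display`. Provenance records the package version, seeds and input
file digests. Inconsistent configurations (e.g. a rig block without all
three roles) fail before any computation.

## Problem sizes

The shipped acceptance run uses a campaign-scale scene chosen as the
package's reference configuration: ten stationary tags × seven 120-min
sessions (≈ 504,000 expected fixes; four sessions before and three after a
simulated update with jitter σ_base 0.15 m → 0.05 m, the regimes implied
by centre-tag precision means of ≈0.19 m and ≈0.06 m), four focal
cow-hours, one 14-min rig walk. Statistical tests use n between 3,600 and
86,400 slots with 3-SE tolerances, 200-replicate recovery checks, and a
10⁶-draw Monte-Carlo oracle for the rig distance under jitter.
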