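# rtlsval

Validation battery for ultra-wideband (UWB) real-time location systems
(RTLS) in livestock barns, plus a synthetic barn/trajectory/error simulator
to exercise it against known ground truth.

Indoor positioning systems — perimeter anchors plus animal-borne tags
reporting (x, y) at a nominal 1 Hz — are increasingly used to monitor dairy
cow behaviour, resource use and social proximity. Before trusting such a
system, a farm or research group needs to quantify four things, and this
package computes all of them from plain CSV position streams:

* **Reliability** — the success rate of positioning: for tag *i* over a
  session of length *T* seconds, `R_i = 100 · n_i / (⌊T⌋ · f)` where `n_i`
  is the number of fixes received and `f` the nominal rate (1 Hz). The
  companion interval analysis summarises the gaps `Δt` between consecutive
  fixes (median, 95th percentile, maximum, and which tags own the longest
  delays).
* **Precision** — dispersion of a stationary tag's fixes about their period
  centroid `c = (x̄, ȳ)`: per-fix error `d_j = ‖p_j − c‖₂`, summarised as
  mean ± SD and as the percent of fixes exceeding reference thresholds
  (0.3 m, a typical supplier accuracy claim, and 2.0 m, roughly one cow
  body length). Under isotropic Gaussian jitter σ the errors are Rayleigh:
  `E[d] = σ√(π/2)`, `P(d > r) = exp(−r²/2σ²)` — used throughout the tests.
* **Proximity concordance** — automatic detection of a moving tag strictly
  within 2 m of a stationary tag, classified against a trained observer's
  15-s focal protocol into four scenarios: congruent, system-missed,
  system-spurious, wrong identity. Accuracy is the percent of observer
  proximity episodes the system matched in every 15-s window.
* **Moving-rig test** — three tags carried on a stick at a fixed 0.3 m
  spacing; wherever all three delivered a fix within the same second, the
  outer→middle distances are compared to the nominal spacing, and the
  walked path is exported as a polyline.

The synthetic module generates ground-truth scenes (stationary tags,
random-waypoint cow walks, rig walks, observer protocols) and corrupts them
with the phenomenological UWB error taxonomy observed in barns: dropout
that worsens towards walls and corners, location-dependent Gaussian jitter,
and rare 2–15 m multipath "reflection jumps".

## Worked example

Precision before and after a provider software update, on a simulated
stationary tag (`python examples/precision_update_effect.py`):

```
pre_update   mean 0.187 +- 0.097 m   >0.3 m: 13.39 %   >2 m: 0.00 %  (n=7200)
post_update  mean 0.062 +- 0.033 m   >0.3 m:  0.00 %   >2 m: 0.00 %  (n=7200)

For isotropic Gaussian jitter the mean centroid distance is sigma*sqrt(pi/2):
expected 0.188 m pre, 0.063 m post — the update roughly triples precision.
```

Each line is one period stratum: the mean ± SD distance of the tag's fixes
to their centroid, and the share of fixes beyond the 0.3 m supplier claim
and the 2 m body-length threshold. The simulated update (jitter σ 0.15 m →
0.05 m) moves the tag from failing to comfortably meeting the 0.3 m claim,
and the measured means match the Rayleigh prediction.

The other examples (`examples/*.py`) walk through reliability and interval
analytics, proximity concordance, the rig walk, trajectory cleaning
(jump filter / median smoothing / gap interpolation), and the assembled
validation report. Everything is also reachable from a thin CLI:

```bash
rtls-validate simulate --mode cow --duration 3600 --seed 7 --out scene
rtls-validate proximity --positions scene_positions.csv \
    --observer scene_observer.csv --session-duration 3600
rtls-validate report --config run.yaml --out report.json
```

The report is a schema-valid JSON document (pydantic;
`rtls-validate schema` prints the JSON schema) with one block per
validation component and provenance (input digests, seeds, version).

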