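"""Trajectory cleaning: jump filter, median smoothing, gap interpolation.

A stationary tag is corrupted with jitter, dropout and 2-15 m reflection
jumps; the example shows how each operator changes the precision figures
and that interpolated fixes never inflate reliability.
"""

from datetime import datetime, timedelta

from rtlsval import (
    ErrorModel,
    Session,
    centroid_distances,
    corrupt_track,
    interpolate_gaps,
    jump_filter,
    median_smooth,
    netluky_layout,
    reliability_rate,
    simulate_stationary_truth,
)

layout = netluky_layout()
start = datetime(2023, 1, 20, 9, 0)
session = Session(start=start, end=start + timedelta(hours=2))

truth = simulate_stationary_truth((15.5, 6.0), session, layout, tag_id="B673")
model = ErrorModel(p_detect_base=0.9, detect_floor=0.0, edge_decay_length=0.0,
                   sigma_base=0.05, sigma_edge=0.0, p_jump=0.01, seed=11)
raw = corrupt_track(truth, model)


def describe(name, stream):
    (res,) = centroid_distances(stream, group_by="session")
    rel = reliability_rate(stream)
    print(f"{name:18s} n={len(stream):5d}  mean {res.mean:.3f} m  "
          f"max {res.max:6.2f} m  >2 m: {res.exceedance[2.0]:.2f} %  "
          f"reliability {rel.rate:.1f} %")


describe("raw", raw)
describe("jump-filtered", jump_filter(raw, min_jump=2.0))
describe("+ median(5)", median_smooth(jump_filter(raw), window=5))
describe("+ interp(3 s)", interpolate_gaps(median_smooth(jump_filter(raw)), max_gap=3.0))

print(
    "\nThe jump filter removes the multi-metre reflection spikes (watch the "
    "max and >2 m columns collapse); the median shrinks residual jitter; "
    "interpolation refills short gaps but, being synthetic, leaves the "
    "reliability figure untouched."
)
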