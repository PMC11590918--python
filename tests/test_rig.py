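from collections import defaultdict

import numpy as np
import pytest

from rtlsval import (
    ErrorModel,
    TagStream,
    corrupt_track,
    export_track_polyline,
    match_same_second,
    rig_distance_summary,
    simulate_rig_walk,
)

from conftest import make_session


def stream(tag, records, sess=None):
    """records: list of (t, x, y)."""
    arr = np.asarray(records, dtype=float)
    sess = sess or make_session(float(np.ceil(arr[:, 0].max())) + 1)
    return TagStream(tag, arr[:, 0], arr[:, 1], arr[:, 2], sess)


def brute_force_triples(lower, middle, upper):
    """Oracle: per-second double loop over all record pairs."""
    buckets = defaultdict(dict)
    for role, s in (("lo", lower), ("mi", middle), ("up", upper)):
        for t, x, y in zip(s.t, s.x, s.y):
            sec = int(np.floor(t))
            if role not in buckets[sec]:
                buckets[sec][role] = (x, y)
    out = []
    for sec in sorted(buckets):
        b = buckets[sec]
        if len(b) == 3:
            out.append((sec, b["lo"], b["mi"], b["up"]))
    return out


class TestMatchSameSecond:
    def test_subsecond_fixes_bucket_by_floor(self):
        lo = stream("L", [(10.2, 0.0, 0.0)])
        mi = stream("M", [(10.9, 0.3, 0.0)])
        up = stream("U", [(10.5, 0.6, 0.0)])
        triples = match_same_second(lower=lo, middle=mi, upper=up)
        assert len(triples) == 1 and triples[0].second == 10

    def test_absent_tag_drops_second(self):
        lo = stream("L", [(10.0, 0, 0), (11.0, 0, 0)])
        mi = stream("M", [(10.5, 0.3, 0)])
        up = stream("U", [(10.7, 0.6, 0), (11.2, 0.6, 0)])
        triples = match_same_second(lower=lo, middle=mi, upper=up)
        assert [t.second for t in triples] == [10]

    def test_count_bounded_by_min_stream(self, layout):
        sess = make_session(400.0)
        lower, mid, upper = simulate_rig_walk(layout, sess, seed=61)
        model = ErrorModel(p_detect_base=0.8, detect_floor=0.0, edge_decay_length=0.0,
                           sigma_base=0.0, sigma_edge=0.0, p_jump=0.0, seed=62)
        streams = [corrupt_track(t, model) for t in (lower, mid, upper)]
        triples = match_same_second(lower=streams[0], middle=streams[1], upper=streams[2])
        assert len(triples) <= min(len(s) for s in streams)

    def test_duplicate_ids_rejected(self):
        a = stream("X", [(0.0, 0, 0)])
        b = stream("X", [(0.0, 1, 0)])
        c = stream("Y", [(0.0, 2, 0)])
        with pytest.raises(ValueError):
            match_same_second(lower=a, middle=b, upper=c)

    def test_oracle_equivalence(self, layout):
        """Matching agrees with a brute-force per-second double loop."""
        rng = np.random.default_rng(63)
        sess = make_session(400.0)
        streams = {}
        for tag in ("L", "M", "U"):
            t = np.sort(rng.uniform(0, 399, size=300))
            t = t[np.diff(t, prepend=-1) > 1e-6]
            streams[tag] = TagStream(tag, t, rng.uniform(0, 31, t.size),
                                     rng.uniform(0, 12, t.size), sess)
        fast = match_same_second(lower=streams["L"], middle=streams["M"], upper=streams["U"])
        slow = brute_force_triples(streams["L"], streams["M"], streams["U"])
        assert len(fast) == len(slow)
        for f, (sec, lo, mi, up) in zip(fast, slow):
            assert f.second == sec
            assert f.lower == pytest.approx(lo)
            assert f.d_lower == pytest.approx(np.hypot(lo[0] - mi[0], lo[1] - mi[1]))

    def test_symmetric_in_record_order(self):
        recs = [(10.2, 0.0, 0.0), (11.4, 1.0, 0.0)]
        lo1 = stream("L", recs)
        lo2 = stream("L", recs)  # same content, separately constructed
        mi = stream("M", [(10.5, 0.3, 0.0), (11.0, 1.3, 0.0)])
        up = stream("U", [(10.8, 0.6, 0.0), (11.9, 1.6, 0.0)])
        assert match_same_second(lower=lo1, middle=mi, upper=up) == match_same_second(
            lower=lo2, middle=mi, upper=up
        )


class TestRigDistanceSummary:
    def test_collinear_nominal(self):
        lo = stream("L", [(0.0, 0.0, 0.0)])
        mi = stream("M", [(0.0, 0.3, 0.0)])
        up = stream("U", [(0.0, 0.6, 0.0)])
        triples = match_same_second(lower=lo, middle=mi, upper=up)
        s = rig_distance_summary(triples)
        assert s.pair_stats["lower"].mean == pytest.approx(0.3)
        assert s.pair_stats["upper"].mean == pytest.approx(0.3)
        assert s.pct_within == 100.0

    def test_noise_free_walk_exact(self, layout):
        sess = make_session(300.0)
        lower, mid, upper = simulate_rig_walk(layout, sess, seed=64)
        clean = ErrorModel(p_detect_base=1.0, detect_floor=1.0, edge_decay_length=0.0,
                           sigma_base=0.0, sigma_edge=0.0, p_jump=0.0)
        triples = match_same_second(
            lower=corrupt_track(lower, clean),
            middle=corrupt_track(mid, clean),
            upper=corrupt_track(upper, clean),
        )
        d = np.array([t.d_lower for t in triples] + [t.d_upper for t in triples])
        np.testing.assert_allclose(d, 0.3, atol=1e-9)

    def test_vanishing_jitter_all_within(self, layout):
        sess = make_session(300.0)
        lower, mid, upper = simulate_rig_walk(layout, sess, seed=65)
        tiny = ErrorModel(p_detect_base=1.0, detect_floor=1.0, edge_decay_length=0.0,
                          sigma_base=1e-6, sigma_edge=0.0, p_jump=0.0, seed=66)
        triples = match_same_second(
            lower=corrupt_track(lower, tiny),
            middle=corrupt_track(mid, tiny),
            upper=corrupt_track(upper, tiny),
        )
        assert rig_distance_summary(triples).pct_within == 100.0

    def test_absolute_rule_flag(self):
        lo = stream("L", [(0.0, 0.0, 0.0)])
        mi = stream("M", [(0.0, 0.5, 0.0)])
        up = stream("U", [(0.0, 1.0, 0.0)])
        triples = match_same_second(lower=lo, middle=mi, upper=up)
        assert rig_distance_summary(triples, rule="deviation").pct_within == 100.0
        assert rig_distance_summary(triples, rule="absolute", tolerance=0.3).pct_within == 0.0

    def test_empty_triples_rejected(self):
        with pytest.raises(ValueError):
            rig_distance_summary([])


class TestPolylineExport:
    def test_vertices_and_order(self):
        s = stream("M", [(0.0, 1.0, 2.0), (1.0, 3.0, 4.0), (50.0, 5.0, 6.0)])
        doc = export_track_polyline(s)
        coords = doc["geometry"]["coordinates"]
        assert coords == [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]  # gap not corrected

    def test_single_fix_degenerate(self):
        s = stream("M", [(0.0, 1.0, 2.0)])
        doc = export_track_polyline(s)
        assert doc["geometry"]["coordinates"] == [[1.0, 2.0]]
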