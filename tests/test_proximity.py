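import numpy as np
import pytest

from rtlsval import (
    BarnLayout,
    ObserverRecord,
    ProximitySeries,
    TagStream,
    classify_concordance,
    episodes_from_series,
    observer_episodes,
    ps_proximity_series,
)

from conftest import make_session


@pytest.fixture
def two_tag_layout():
    return BarnLayout(
        width=20,
        depth=10,
        stationary_tags={"A": (5.0, 5.0, 1.0), "B": (12.0, 5.0, 1.0)},
    )


def stream_at(points, sess=None, tag="cow"):
    pts = np.asarray(points, dtype=float)
    sess = sess or make_session(float(len(pts)) + 1)
    return TagStream(tag, np.arange(len(pts), dtype=float), pts[:, 0], pts[:, 1], sess)


def series_of(assignments, focal="cow", radius=2.0):
    """Build a ProximitySeries directly from (t, tag) pairs."""
    t = np.array([a[0] for a in assignments], dtype=float)
    tag = np.array([a[1] for a in assignments], dtype=object)
    dist = np.where([g is not None for g in tag], 1.0, np.nan)
    return ProximitySeries(focal, t, tag, dist, radius)


class TestProximitySeries:
    def test_within_radius_assigned(self, two_tag_layout):
        s = ps_proximity_series(stream_at([(6.0, 5.0)]), two_tag_layout)
        assert s.tag[0] == "A" and s.distance[0] == pytest.approx(1.0)

    def test_beyond_radius_none(self, two_tag_layout):
        s = ps_proximity_series(stream_at([(8.0, 5.0)]), two_tag_layout)
        assert s.tag[0] is None

    def test_nearest_wins(self, two_tag_layout):
        # 1.0 m from B, 6.0 m from A
        s = ps_proximity_series(stream_at([(11.0, 5.0)]), two_tag_layout)
        assert s.tag[0] == "B"

    def test_equidistant_tie_lexicographic(self, two_tag_layout):
        s = ps_proximity_series(stream_at([(8.5, 5.0)]), two_tag_layout, radius=4.0)
        assert s.tag[0] == "A"

    def test_boundary_strictly_inside(self, two_tag_layout):
        s = ps_proximity_series(stream_at([(7.0, 5.0)]), two_tag_layout)  # exactly 2.0 m
        assert s.tag[0] is None


class TestEpisodes:
    def test_simple_run(self):
        eps = episodes_from_series(series_of([(0, "A"), (1, "A"), (2, "A")]))
        assert len(eps) == 1
        assert (eps[0].start, eps[0].end, eps[0].tag_id) == (0.0, 2.0, "A")

    def test_long_gap_splits(self):
        eps = episodes_from_series(series_of([(0, "A"), (1, "A"), (5, "A")]), max_gap=2)
        assert len(eps) == 2

    def test_short_gap_bridged(self):
        eps = episodes_from_series(series_of([(0, "A"), (1, None), (2, "A")]), max_gap=2)
        assert len(eps) == 1 and eps[0].end == 2.0

    def test_other_tag_breaks_run(self):
        eps = episodes_from_series(series_of([(0, "A"), (1, "B"), (2, "A")]))
        assert [e.tag_id for e in eps] == ["A", "B", "A"]


class TestObserverEpisodes:
    def recs(self, tags, focal="cow"):
        return [
            ObserverRecord(focal, 15.0 * i, tag) for i, tag in enumerate(tags)
        ]

    def test_run_with_trailing_none(self):
        eps = observer_episodes(self.recs(["A", "A", None]))
        assert len(eps) == 1
        assert (eps[0].start, eps[0].end) == (0.0, 30.0)

    def test_adjacent_tags_touch(self):
        eps = observer_episodes(self.recs(["A", "B"]))
        assert len(eps) == 2
        assert eps[0].end == eps[1].start == 15.0

    def test_all_none_empty(self):
        assert observer_episodes(self.recs([None, None])) == []

    def test_skipped_grid_step_splits(self):
        recs = [ObserverRecord("cow", 0.0, "A"), ObserverRecord("cow", 45.0, "A")]
        assert len(observer_episodes(recs)) == 2


def fixes(spec):
    """spec: list of (second, tag) -> one fix per second assigned to tag."""
    return series_of([(float(s), g) for s, g in spec])


def obs_recs(tags):
    return [ObserverRecord("cow", 15.0 * i, g) for i, g in enumerate(tags)]


class TestClassifyConcordance:
    def test_perfect_agreement(self):
        ps = fixes([(s, "A") for s in range(30)] + [(s, None) for s in range(30, 60)])
        rep = classify_concordance(ps, obs_recs(["A", "A", None, None]))
        assert rep.summary.accuracy == 100.0
        assert rep.summary.scenario_counts == {1: 1, 2: 0, 3: 0, 4: 0}
        assert rep.summary.total_error_duration == 0.0

    def test_system_missed_is_scenario_2(self):
        ps = fixes([(s, None) for s in range(60)])
        rep = classify_concordance(ps, obs_recs(["A", "A", None, None]))
        (case,) = [c for c in rep.cases if c.scenario != 3]
        assert case.scenario == 2
        assert case.error_duration == 30.0  # whole episode missed

    def test_wrong_identity_is_scenario_4(self):
        ps = fixes([(s, "B") for s in range(60)])
        rep = classify_concordance(ps, obs_recs(["A", "A", None, None]))
        obs_cases = [c for c in rep.cases if c.scenario in (1, 2, 4)]
        assert [c.scenario for c in obs_cases] == [4]
        assert obs_cases[0].ps_verdict == "B"
        # the same system fixes are spurious in the observer-free windows
        assert rep.summary.scenario_counts[3] == 1

    def test_spurious_is_scenario_3(self):
        ps = fixes([(s, None) for s in range(30)] + [(s, "B") for s in range(30, 60)])
        rep = classify_concordance(ps, obs_recs([None, None, None, None]))
        assert rep.summary.scenario_counts == {1: 0, 2: 0, 3: 1, 4: 0}
        (case,) = rep.cases
        assert case.tag_id == "B" and case.error_duration == 30.0

    def test_partial_miss_counts_window(self):
        # system in proximity for the first window only of a two-window episode
        ps = fixes([(s, "A") for s in range(15)] + [(s, None) for s in range(15, 60)])
        rep = classify_concordance(ps, obs_recs(["A", "A", None, None]))
        (case,) = [c for c in rep.cases if c.scenario != 3]
        assert case.scenario == 2
        assert case.error_duration == 15.0

    def test_error_duration_conservation(self):
        ps = fixes(
            [(s, "A") for s in range(15)]
            + [(s, "B") for s in range(15, 30)]
            + [(s, None) for s in range(30, 45)]
            + [(s, "A") for s in range(45, 60)]
        )
        rep = classify_concordance(ps, obs_recs(["A", "A", "A", None]))
        mismatched_windows = 2  # windows 2 and 3 disagree with observer A; window 4 spurious
        spurious_windows = 1
        assert rep.summary.total_error_duration == 15.0 * (mismatched_windows + spurious_windows)

    def test_disjoint_spans_rejected(self):
        ps = fixes([(s, "A") for s in range(10)])
        recs = [ObserverRecord("cow", 600.0, "A")]
        with pytest.raises(ValueError):
            classify_concordance(ps, recs)

    def test_scenario_percentages_sum(self):
        ps = fixes(
            [(s, "A") for s in range(30)]
            + [(s, None) for s in range(30, 45)]
            + [(s, "B") for s in range(45, 60)]
        )
        rep = classify_concordance(ps, obs_recs(["A", "A", "B", None]))
        counts = rep.summary.scenario_counts
        n_obs = rep.summary.n_observer_cases
        assert counts[1] + counts[2] + counts[4] == n_obs


class TestRadiusExtremes:
    def test_tiny_radius_all_missed(self, two_tag_layout):
        sess = make_session(70.0)
        pts = [(5.5, 5.0)] * 60  # 0.5 m from tag A
        stream = stream_at(pts, sess)
        obs = obs_recs(["A", "A", "A", "A"])
        series = ps_proximity_series(stream, two_tag_layout, radius=1e-9)
        rep = classify_concordance(series, obs)
        assert rep.summary.scenario_counts[2] == rep.summary.n_observer_cases

    def test_huge_radius_never_none(self, two_tag_layout):
        rng = np.random.default_rng(51)
        pts = np.column_stack([rng.uniform(0, 20, 60), rng.uniform(0, 10, 60)])
        series = ps_proximity_series(stream_at(pts), two_tag_layout, radius=1e3)
        assert all(g is not None for g in series.tag)
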