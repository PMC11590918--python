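"""Proximity detection and observer concordance.

A moving (cow-borne) tag is "in proximity" of a stationary reference tag
when their 2D distance is strictly below a threshold radius — 2 m by
default, roughly one cow body length.  The positioning system's verdicts
are compared against a trained observer's 15-s focal protocol, the
reference, using four agreement scenarios:

1. congruent — system and observer agree (same tag, or both none);
2. system missed — the observer saw a proximity the system did not report;
3. system spurious — the system reported a proximity the observer did not see;
4. wrong identity — both saw a proximity but to different tags.

The unit of assessment (a "case") is a maximal observer episode: an
unbroken run of protocol records carrying the same tag.  Within an episode
the system's verdict is evaluated per 15-s window (modal in-proximity tag
among the window's fixes, ties conservatively to none); an episode is
congruent only if every window matches, and the error duration of a
non-congruent case is the summed length of its mismatched windows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import BarnLayout, ObserverRecord, TagStream

__all__ = [
    "ProximitySeries",
    "ProximityEpisode",
    "ConcordanceCase",
    "ConcordanceSummary",
    "ConcordanceReport",
    "ps_proximity_series",
    "episodes_from_series",
    "observer_episodes",
    "classify_concordance",
]


@dataclass
class ProximitySeries:
    """Per-fix nearest-stationary-tag assignment for one focal tag."""

    focal_id: str
    t: np.ndarray
    tag: np.ndarray  # object array: tag id or None per fix
    distance: np.ndarray  # metres to assigned tag; nan when unassigned
    radius: float

    def __post_init__(self):
        assigned = np.array([g is not None for g in self.tag], dtype=bool)
        if np.any(self.distance[assigned] >= self.radius):
            raise ValueError("assigned distance must be strictly below the radius")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class ProximityEpisode:
    """Maximal proximity run of one focal near one stationary tag."""

    source: str  # "PS" or "observer"
    focal_id: str
    tag_id: str
    start: float
    end: float

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("episode end before start")
        if self.source not in ("PS", "observer"):
            raise ValueError(f"unknown episode source {self.source!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ConcordanceCase:
    """One classified agreement case.

    Scenarios 1/2/4 are anchored on an observer episode; scenario 3 on a
    system episode with no observer counterpart.  ``error_duration`` is zero
    exactly for congruent cases.
    """

    focal_id: str
    tag_id: str  # observer tag for 1/2/4; system tag for 3
    scenario: int
    start: float
    end: float
    error_duration: float
    ps_verdict: str | None  # modal mismatched verdict (scenarios 2/4), else None

    def __post_init__(self):
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1..4")
        if (self.scenario == 1) != (self.error_duration == 0.0):
            raise ValueError("scenario 1 iff zero error duration")


@dataclass(frozen=True)
class ConcordanceSummary:
    """Aggregate concordance over one focal comparison."""

    n_observer_cases: int
    scenario_counts: Mapping[int, int]
    accuracy: float  # percent of observer cases congruent
    error_duration_by_scenario: Mapping[int, float]  # seconds
    error_duration_by_tag: Mapping[str, float]  # seconds
    total_error_duration: float


@dataclass(frozen=True)
class ConcordanceReport:
    cases: tuple[ConcordanceCase, ...]
    summary: ConcordanceSummary


def ps_proximity_series(
    focal: TagStream, layout: BarnLayout, radius: float = 2.0
) -> ProximitySeries:
    """Assign each fix the nearest stationary tag strictly within ``radius``.

    Ties at exactly equal distance resolve to the lexicographically smallest
    tag id, for determinism.
    """
    ids, xy = layout.stationary_xy()
    if not ids:
        raise ValueError("layout has no stationary tags")
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(focal)
    tag = np.full(n, None, dtype=object)
    dist = np.full(n, np.nan)
    if n:
        d = np.hypot(
            focal.x[:, None] - xy[None, :, 0], focal.y[:, None] - xy[None, :, 1]
        )
        j = d.argmin(axis=1)  # first minimum -> smallest id (ids sorted)
        dmin = d[np.arange(n), j]
        within = dmin < radius
        tag[within] = np.array(ids, dtype=object)[j[within]]
        dist[within] = dmin[within]
    return ProximitySeries(focal.tag_id, focal.t.copy(), tag, dist, radius)


def episodes_from_series(
    series: ProximitySeries, max_gap: float = 2.0
) -> list[ProximityEpisode]:
    """Maximal same-tag runs of a proximity series, bridging short gaps.

    Consecutive assignments to the same tag are merged when separated by at
    most ``max_gap`` seconds, even across unassigned fixes in between; an
    intervening assignment to a *different* tag always breaks the run.
    Unassigned stretches produce no episode.
    """
    episodes: list[ProximityEpisode] = []
    cur_tag: str | None = None
    cur_start = cur_end = 0.0
    for t, g in zip(series.t, series.tag):
        if g is None:
            continue
        if cur_tag is not None and g == cur_tag and t - cur_end <= max_gap:
            cur_end = float(t)
            continue
        if cur_tag is not None:
            episodes.append(
                ProximityEpisode("PS", series.focal_id, cur_tag, cur_start, cur_end)
            )
        cur_tag = str(g)
        cur_start = cur_end = float(t)
    if cur_tag is not None:
        episodes.append(
            ProximityEpisode("PS", series.focal_id, cur_tag, cur_start, cur_end)
        )
    return episodes


def observer_episodes(
    records: Sequence[ObserverRecord], grid: float = 15.0
) -> list[ProximityEpisode]:
    """Maximal runs of consecutive same-tag protocol records.

    Records must be sorted and grid-aligned; a run ends when the tag changes
    or a grid step is skipped.  The episode covers ``[first record t,
    last record t + grid]`` — each record stands for the interval it opens.
    ``None`` records produce no episode.
    """
    episodes: list[ProximityEpisode] = []
    cur: list[ObserverRecord] = []

    def flush():
        if cur:
            episodes.append(
                ProximityEpisode(
                    "observer", cur[0].focal_id, cur[0].proximate_tag,  # type: ignore[arg-type]
                    cur[0].t, cur[-1].t + grid,
                )
            )
            cur.clear()

    for r in records:
        if r.proximate_tag is None:
            flush()
            continue
        if cur and (
            r.proximate_tag != cur[-1].proximate_tag
            or r.focal_id != cur[-1].focal_id
            or abs(r.t - cur[-1].t - grid) > 1e-6
        ):
            flush()
        cur.append(r)
    flush()
    return episodes


def _window_verdicts(
    series: ProximitySeries, starts: np.ndarray, grid: float
) -> list[str | None]:
    """Modal in-proximity tag per window [t, t+grid); ties and no-fix -> None."""
    verdicts: list[str | None] = []
    for t0 in starts:
        m = (series.t >= t0) & (series.t < t0 + grid)
        tags = [g for g in series.tag[m] if g is not None]
        if not tags:
            verdicts.append(None)
            continue
        counts = Counter(tags).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            verdicts.append(None)  # ambiguous window: conservative against the system
        else:
            verdicts.append(counts[0][0])
    return verdicts


def classify_concordance(
    ps: ProximitySeries,
    obs: Sequence[ObserverRecord],
    grid: float = 15.0,
) -> ConcordanceReport:
    """Classify every observer episode (and spurious system run) into scenarios.

    Each observer episode is evaluated window by window against the system's
    modal verdicts.  An episode with every window matching is congruent
    (scenario 1).  Otherwise the modal verdict among the *mismatched*
    windows decides: mostly-none → scenario 2 (system missed), mostly some
    other tag → scenario 4 (wrong identity); ties fall to scenario 2.  Grid
    windows where the observer recorded no proximity but the system's
    verdict names a tag form scenario-3 (spurious) cases, one per maximal
    run.  Error durations count mismatched windows at full window length.
    """
    obs = sorted(obs, key=lambda r: r.t)
    if not obs or len(ps) == 0:
        raise ValueError("need both system fixes and observer records")
    if ps.t.max() < obs[0].t or ps.t.min() >= obs[-1].t + grid:
        raise ValueError("system stream and observer protocol do not overlap in time")

    starts = np.array([r.t for r in obs])
    verdicts = _window_verdicts(ps, starts, grid)
    verdict_at = dict(zip(starts.tolist(), verdicts))
    obs_at = {r.t: r.proximate_tag for r in obs}

    cases: list[ConcordanceCase] = []
    for ep in observer_episodes(obs, grid=grid):
        w = np.arange(ep.start, ep.end - grid / 2, grid)
        mism = [verdict_at[t0] for t0 in w if verdict_at[t0] != ep.tag_id]
        if not mism:
            cases.append(
                ConcordanceCase(ep.focal_id, ep.tag_id, 1, ep.start, ep.end, 0.0, None)
            )
            continue
        counts = Counter("NONE" if v is None else v for v in mism).most_common()
        top, top_n = counts[0]
        tied = [c for c, k in counts if k == top_n]
        if top == "NONE" or "NONE" in tied and len(tied) > 1:
            scenario, verdict = 2, None
        else:
            scenario, verdict = 4, top
        cases.append(
            ConcordanceCase(
                ep.focal_id, ep.tag_id, scenario, ep.start, ep.end,
                grid * len(mism), verdict,
            )
        )

    # scenario 3: system proximity in windows the observer marked free
    run: list[tuple[float, str]] = []
    for t0, v in zip(starts, verdicts):
        if obs_at[t0] is None and v is not None:
            if run and abs(t0 - run[-1][0] - grid) > 1e-6:
                cases.append(_spurious_case(ps.focal_id, run, grid))
                run = []
            run.append((float(t0), v))
        elif run:
            cases.append(_spurious_case(ps.focal_id, run, grid))
            run = []
    if run:
        cases.append(_spurious_case(ps.focal_id, run, grid))

    obs_cases = [c for c in cases if c.scenario != 3]
    n_obs = len(obs_cases)
    counts = {k: sum(1 for c in cases if c.scenario == k) for k in (1, 2, 3, 4)}
    err_by_scen = {
        k: float(sum(c.error_duration for c in cases if c.scenario == k))
        for k in (1, 2, 3, 4)
    }
    err_by_tag: dict[str, float] = {}
    for c in cases:
        if c.error_duration:
            err_by_tag[c.tag_id] = err_by_tag.get(c.tag_id, 0.0) + c.error_duration
    summary = ConcordanceSummary(
        n_observer_cases=n_obs,
        scenario_counts=counts,
        accuracy=100.0 * counts[1] / n_obs if n_obs else float("nan"),
        error_duration_by_scenario=err_by_scen,
        error_duration_by_tag=err_by_tag,
        total_error_duration=float(sum(err_by_scen.values())),
    )
    return ConcordanceReport(tuple(cases), summary)


def _spurious_case(focal_id: str, run: list[tuple[float, str]], grid: float) -> ConcordanceCase:
    tags = Counter(v for _, v in run)
    tag = sorted(tags, key=lambda g: (-tags[g], g))[0]
    start = run[0][0]
    end = run[-1][0] + grid
    return ConcordanceCase(focal_id, tag, 3, start, end, grid * len(run), None)
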