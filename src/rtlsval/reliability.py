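"""Positioning reliability: success rates and inter-measurement intervals.

Reliability of a tag over a session is the ratio of fixes actually recorded
to the number expected at the system's nominal sampling rate (1 Hz by
default).  The interval analysis characterises the time differences between
consecutive fixes of a tag — their central tendency, upper tail, and which
tags account for the longest delays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import Session, TagStream

__all__ = [
    "ReliabilityResult",
    "IntervalStats",
    "expected_count",
    "reliability_rate",
    "interval_stats",
]


@dataclass(frozen=True)
class ReliabilityResult:
    """Success rate of positioning for one tag over one session."""

    tag_id: str
    period_label: str
    actual_count: int
    expected_count: int
    rate: float  # percent

    def __post_init__(self):
        if not 0.0 <= self.rate <= 100.0 + 1e-9:
            raise ValueError(f"rate {self.rate} outside [0, 100]")


@dataclass(frozen=True)
class IntervalStats:
    """Summary of consecutive-fix time differences pooled over streams."""

    n_diffs: int
    mean: float
    sd: float
    median: float
    p95: float
    max: float
    top_quantile: float
    top_quantile_threshold: float
    per_tag_share_of_long_delays: Mapping[str, float]  # percent, sums to 100

    def __post_init__(self):
        if not self.median <= self.p95 <= self.max + 1e-12:
            raise ValueError("quantiles out of order")


def expected_count(session: Session) -> int:
    """Expected number of fixes: floor of the session length times the rate."""
    return int(math.floor(session.duration) * session.nominal_rate)


def reliability_rate(stream: TagStream) -> ReliabilityResult:
    """Percent of expected fixes the system actually recorded.

    Synthetic (interpolated) fixes never count toward reliability.
    """
    expected = expected_count(stream.session)
    if expected == 0:
        raise ValueError("session too short: expected count is zero")
    actual = stream.n_measured
    return ReliabilityResult(
        tag_id=stream.tag_id,
        period_label=stream.session.period_label,
        actual_count=actual,
        expected_count=expected,
        rate=100.0 * actual / expected,
    )


def interval_stats(
    streams: Sequence[TagStream], long_quantile: float = 0.99
) -> IntervalStats:
    """Pooled consecutive-interval statistics with a long-delay attribution.

    Differences are taken within each tag-session stream only — session
    boundaries never create artificial gaps.  The long-delay threshold is
    the empirical ``long_quantile`` of the pooled differences; each tag's
    share of the differences above it is reported as a percent of all long
    delays.
    """
    if not 0.0 < long_quantile < 1.0:
        raise ValueError("long_quantile must be in (0, 1)")
    diffs = []
    tags = []
    for s in streams:
        if len(s) < 2:
            continue
        d = np.diff(s.t)
        diffs.append(d)
        tags.append(np.full(d.size, s.tag_id, dtype=object))
    if not diffs:
        raise ValueError("need at least one stream with two or more fixes")
    pooled = np.concatenate(diffs)
    tag_of = np.concatenate(tags)
    threshold = float(np.quantile(pooled, long_quantile))
    long = pooled > threshold
    shares: dict[str, float] = {}
    n_long = int(long.sum())
    if n_long:
        for tag in np.unique(tag_of[long]):
            shares[str(tag)] = 100.0 * int((long & (tag_of == tag)).sum()) / n_long
    return IntervalStats(
        n_diffs=int(pooled.size),
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        median=float(np.median(pooled)),
        p95=float(np.quantile(pooled, 0.95)),
        max=float(pooled.max()),
        top_quantile=long_quantile,
        top_quantile_threshold=threshold,
        per_tag_share_of_long_delays=shares,
    )
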