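"""Positioning precision: dispersion of fixes about their period centroid.

Precision (the study's "accuracy") of a stationary tag is measured without
surveyed ground truth: all fixes recorded in an observation period are
reduced to their centroid (component-wise arithmetic mean), and the
Euclidean distance of every fix to that centroid is the per-fix error.
Summaries report the mean, SD and range of those distances plus the percent
of fixes exceeding reference thresholds — by default 0.3 m (the supplier's
declared accuracy) and 2.0 m (roughly one cow body length).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Mapping, Sequence

import numpy as np

from .data_model import TagStream

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PrecisionResult",
    "StratumSummary",
    "centroid",
    "centroid_distances",
    "pooled_exceedance_shares",
    "stratified_precision",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.3, 2.0)


@dataclass(frozen=True)
class PrecisionResult:
    """Centroid-distance summary of one tag over one grouping period."""

    tag_id: str
    group_key: str  # ISO date for group_by="day", session label otherwise
    period_label: str
    centroid: tuple[float, float]
    distances: np.ndarray  # metres, one per fix
    mean: float
    sd: float
    min: float
    max: float
    exceedance: Mapping[float, float]  # threshold -> percent of fixes above

    def __post_init__(self):
        exc = dict(sorted(self.exceedance.items()))
        object.__setattr__(self, "exceedance", exc)
        vals = list(exc.values())
        if any(b > a + 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError("exceedance must be non-increasing in threshold")


@dataclass(frozen=True)
class StratumSummary:
    """Pooled precision over one period-label stratum."""

    period_label: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    exceedance: Mapping[float, float]
    per_tag_share_of_gross_errors: Mapping[str, float]  # percent at top threshold


def centroid(points: Sequence[tuple[float, float]] | np.ndarray) -> tuple[float, float]:
    """Component-wise arithmetic mean of 2D points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        raise ValueError("centroid of an empty point set is undefined")
    c = pts.mean(axis=0)
    return float(c[0]), float(c[1])


def _summarise(dist: np.ndarray, thresholds: Sequence[float]) -> dict:
    return {
        "mean": float(dist.mean()),
        "sd": float(dist.std(ddof=1)) if dist.size > 1 else 0.0,
        "min": float(dist.min()),
        "max": float(dist.max()),
        "exceedance": {
            float(th): 100.0 * float((dist > th).mean()) for th in sorted(thresholds)
        },
    }


def centroid_distances(
    stream: TagStream,
    group_by: str = "day",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[PrecisionResult]:
    """Per-group centroid distances of one stream's fixes.

    ``group_by="day"`` groups fixes by the calendar day of the session's
    local clock (the observation-period reading); ``"session"`` treats the
    whole stream as one group.  The centroid of each group is computed from
    the same fixes it is compared against.
    """
    if len(stream) == 0:
        raise ValueError("stream is empty")
    if group_by not in ("day", "session"):
        raise ValueError(f"unknown group_by {group_by!r}")
    if group_by == "day":
        start = stream.session.start
        days = np.array(
            [(start + timedelta(seconds=float(t))).date().isoformat() for t in stream.t]
        )
        keys = sorted(set(days))
        groups = [(k, days == k) for k in keys]
    else:
        label = stream.session.period_label or "session"
        groups = [(label, np.ones(len(stream), dtype=bool))]

    results = []
    for key, mask in groups:
        xs = stream.x[mask]
        ys = stream.y[mask]
        cx, cy = centroid(np.column_stack([xs, ys]))
        dist = np.hypot(xs - cx, ys - cy)
        s = _summarise(dist, thresholds)
        results.append(
            PrecisionResult(
                tag_id=stream.tag_id,
                group_key=str(key),
                period_label=stream.session.period_label,
                centroid=(cx, cy),
                distances=dist,
                **s,
            )
        )
    return results


def pooled_exceedance_shares(
    results: Sequence[PrecisionResult], threshold: float
) -> dict[str, float]:
    """Each tag's percent share of all fixes beyond ``threshold`` (gross errors)."""
    counts: dict[str, int] = {}
    total = 0
    for r in results:
        k = int((r.distances > threshold).sum())
        if k:
            counts[r.tag_id] = counts.get(r.tag_id, 0) + k
            total += k
    return {tag: 100.0 * k / total for tag, k in counts.items()} if total else {}


def stratified_precision(
    results: Sequence[PrecisionResult],
    by: Sequence[str] | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[str, StratumSummary]:
    """Pooled precision per period-label stratum (description, no inference).

    ``by`` optionally restricts and validates the labels: a result carrying
    a label not listed raises.  Strata with no results are absent from the
    output, never reported as zero.
    """
    if not results:
        raise ValueError("no precision results to stratify")
    if by is not None:
        allowed = set(by)
        for r in results:
            if r.period_label not in allowed:
                raise ValueError(f"unknown period label {r.period_label!r}")
    labels = list(dict.fromkeys(r.period_label for r in results))
    out: dict[str, StratumSummary] = {}
    top = max(thresholds)
    for label in labels:
        sub = [r for r in results if r.period_label == label]
        dist = np.concatenate([r.distances for r in sub])
        s = _summarise(dist, thresholds)
        out[label] = StratumSummary(
            period_label=label,
            n=int(dist.size),
            per_tag_share_of_gross_errors=pooled_exceedance_shares(sub, top),
            **s,
        )
    return out
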