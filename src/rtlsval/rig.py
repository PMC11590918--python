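"""Dynamic moving-rig test: three tags at fixed 0.3 m spacing on a stick.

A carrier walks a stick through the barn with three tags mounted 0.3 m
apart.  For every second in which all three tags delivered a fix, the
distances from each outer tag to the middle one are computed and compared
against the nominal spacing; the reconstruction of the walked path is
exported as a plain polyline (consecutive fixes joined, no gap correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import TagStream
from .reliability import reliability_rate

__all__ = [
    "MatchedTriple",
    "RigPairStats",
    "RigSummary",
    "match_same_second",
    "rig_distance_summary",
    "export_track_polyline",
]


@dataclass(frozen=True)
class MatchedTriple:
    """Positions of all three rig tags within one whole second."""

    second: int
    lower: tuple[float, float]
    middle: tuple[float, float]
    upper: tuple[float, float]
    d_lower: float  # lower tag -> middle tag, metres
    d_upper: float  # upper tag -> middle tag, metres


@dataclass(frozen=True)
class RigPairStats:
    """Distance statistics for one outer tag against the middle tag."""

    tag_id: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class RigSummary:
    n_triples: int
    nominal: float
    tolerance: float
    rule: str
    pair_stats: Mapping[str, RigPairStats]  # keys "lower", "upper"
    pct_within: float  # pooled percent of distances meeting the rule
    reliability: Mapping[str, float] | None  # role -> percent, if streams given


def _first_fix_per_second(stream: TagStream) -> dict[int, tuple[float, float]]:
    out: dict[int, tuple[float, float]] = {}
    for t, x, y in zip(stream.t, stream.x, stream.y):
        s = int(np.floor(t))
        if s not in out:
            out[s] = (float(x), float(y))
    return out


def match_same_second(
    *, lower: TagStream, middle: TagStream, upper: TagStream
) -> list[MatchedTriple]:
    """Pair the three rig streams second by second.

    Fixes are bucketed by ``floor(t)``; a triple is emitted for every second
    in which all three tags have at least one fix (the first fix of a tag
    within the second is used).  Roles are declared by keyword; tag ids must
    be distinct.
    """
    ids = {lower.tag_id, middle.tag_id, upper.tag_id}
    if len(ids) != 3:
        raise ValueError("rig streams must have three distinct tag ids")
    lo = _first_fix_per_second(lower)
    mi = _first_fix_per_second(middle)
    up = _first_fix_per_second(upper)
    triples = []
    for s in sorted(lo.keys() & mi.keys() & up.keys()):
        pl, pm, pu = lo[s], mi[s], up[s]
        triples.append(
            MatchedTriple(
                second=s,
                lower=pl,
                middle=pm,
                upper=pu,
                d_lower=float(np.hypot(pl[0] - pm[0], pl[1] - pm[1])),
                d_upper=float(np.hypot(pu[0] - pm[0], pu[1] - pm[1])),
            )
        )
    return triples


def rig_distance_summary(
    triples: Sequence[MatchedTriple],
    nominal: float = 0.3,
    tolerance: float = 0.3,
    rule: str = "deviation",
    streams: Mapping[str, TagStream] | None = None,
) -> RigSummary:
    """Distance statistics of the matched triples against the nominal spacing.

    ``rule="deviation"`` counts a distance as meeting the specification when
    ``|d - nominal| <= tolerance`` (deviation within the supplier's declared
    accuracy); ``rule="absolute"`` when ``d <= tolerance``.  If the three
    streams are supplied (keys ``lower``/``middle``/``upper``) the per-tag
    reliability over the walk session is reported alongside.
    """
    if not triples:
        raise ValueError("no matched triples")
    if nominal <= 0 or tolerance <= 0:
        raise ValueError("nominal and tolerance must be positive")
    if rule not in ("deviation", "absolute"):
        raise ValueError(f"unknown rule {rule!r}")
    d_lower = np.array([tr.d_lower for tr in triples])
    d_upper = np.array([tr.d_upper for tr in triples])
    pooled = np.concatenate([d_lower, d_upper])
    if rule == "deviation":
        ok = np.abs(pooled - nominal) <= tolerance
    else:
        ok = pooled <= tolerance

    def stats(d: np.ndarray, tag_id: str) -> RigPairStats:
        return RigPairStats(
            tag_id=tag_id,
            n=int(d.size),
            mean=float(d.mean()),
            sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
            min=float(d.min()),
            max=float(d.max()),
        )

    reliability = None
    if streams is not None:
        for role in ("lower", "middle", "upper"):
            if role not in streams:
                raise ValueError(f"missing stream for role {role!r}")
        reliability = {
            role: reliability_rate(streams[role]).rate
            for role in ("lower", "middle", "upper")
        }
    lower_id = streams["lower"].tag_id if streams else "lower"
    upper_id = streams["upper"].tag_id if streams else "upper"
    return RigSummary(
        n_triples=len(triples),
        nominal=nominal,
        tolerance=tolerance,
        rule=rule,
        pair_stats={
            "lower": stats(d_lower, lower_id),
            "upper": stats(d_upper, upper_id),
        },
        pct_within=100.0 * float(ok.mean()),
        reliability=reliability,
    )


def export_track_polyline(stream: TagStream) -> dict:
    """A GeoJSON LineString Feature joining consecutive fixes in order.

    No gap correction or interpolation is applied: long dropouts appear as
    straight chords, reproducing the raw path-reconstruction view.
    Coordinates are barn metres.
    """
    coords = [[float(x), float(y)] for x, y in zip(stream.x, stream.y)]
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {
            "tag_id": stream.tag_id,
            "n_fixes": len(stream),
            "crs": "barn metres, origin lower-left",
        },
    }
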