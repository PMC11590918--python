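"""Domain types and file I/O for barn positioning data.

The pipeline's universal currency is the :class:`TagStream`: the timestamped
2D fixes one ultra-wideband tag produced during one recording session.
Alongside it live the barn geometry (:class:`BarnLayout`), the recording
session metadata (:class:`Session`) and the 15-s focal-observation protocol
(:class:`ObserverRecord`), plus CSV/YAML readers and writers for all of them.

Coordinate frame: origin at the lower-left barn corner, x along the long
axis, y along the short axis, metres.  Heights (z) are stored only for
anchors and stationary-tag placements; position streams are strictly 2D.
Timestamps are ISO-8601 in files and seconds since the session start
internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "RowError",
    "GridError",
    "PositionRecord",
    "Session",
    "TagStream",
    "BarnLayout",
    "ObserverRecord",
    "ParseReport",
    "NONE_TOKENS",
    "read_position_table",
    "write_position_table",
    "read_observer_table",
    "write_observer_table",
    "netluky_layout",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class RowError(ValueError):
    """A specific row of an input file could not be parsed.

    Carries the 1-based physical line number (header = line 1).
    """

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class GridError(ValueError):
    """An observer-protocol timestamp is off the sampling grid."""


#: tokens in observer files that normalise to "no tag in proximity"
NONE_TOKENS = frozenset({"", "none", "nan", "na", "-"})


@dataclass(frozen=True)
class PositionRecord:
    """One 2D fix of one tag.

    ``t`` is in seconds since the stream epoch (the session start);
    sub-second resolution is allowed.
    """

    tag_id: str
    t: float
    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for tag {self.tag_id}")
        if self.t < 0:
            raise ValueError(f"negative timestamp {self.t} for tag {self.tag_id}")


@dataclass(frozen=True)
class Session:
    """One recording session: the denominator of every reliability figure.

    Parameters
    ----------
    start, end
        Wall-clock bounds of the session; ``end`` must be after ``start``.
    period_label
        Free-form stratification label, e.g. ``"pre_update"`` /
        ``"post_update"`` for before/after a provider software update.
    nominal_rate
        Fixes per second the system is configured to deliver (default 1 Hz).
    """

    start: datetime
    end: datetime
    period_label: str = ""
    nominal_rate: float = 1.0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("session end must be after start")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return (self.end - self.start).total_seconds()


@dataclass
class TagStream:
    """All fixes of one tag in one session, sorted by time.

    Coordinates and timestamps are stored as parallel numpy arrays;
    timestamps are strictly increasing (duplicates are collapsed on
    ingest).  ``synthetic`` marks fixes inserted by gap interpolation —
    they never count toward reliability.
    """

    tag_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    session: Session
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if self.synthetic is None:
            self.synthetic = np.zeros(self.t.shape, dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)
            if self.synthetic.shape != self.t.shape:
                raise ValueError("synthetic mask length mismatch")
        if self.t.size:
            if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
                raise ValueError("non-finite coordinates")
            if np.any(self.t < 0):
                raise ValueError("negative timestamps")
            if np.any(np.diff(self.t) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def n_measured(self) -> int:
        """Number of fixes actually recorded by the system (non-synthetic)."""
        return int(np.count_nonzero(~self.synthetic))

    def records(self) -> list[PositionRecord]:
        return [
            PositionRecord(self.tag_id, float(t), float(x), float(y))
            for t, x, y in zip(self.t, self.x, self.y)
        ]

    def replace(self, **kwargs) -> "TagStream":
        """Return a copy with the given fields replaced (arrays re-validated)."""
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ObserverRecord:
    """One 15-s focal-protocol entry.

    ``t`` is the interval start in seconds since the protocol epoch, aligned
    to the grid; ``proximate_tag`` is the stationary tag the focal animal was
    within the proximity zone of, or ``None``.
    """

    focal_id: str
    t: float
    proximate_tag: str | None


@dataclass(frozen=True)
class BarnLayout:
    """Rectangular barn geometry: anchors, named zones, stationary tags.

    ``zones`` maps a zone name to an axis-aligned rectangle
    ``(x0, y0, x1, y1)``; ``stationary_tags`` maps a tag id to its installed
    ``(x, y, height)``.  All placements must lie inside the barn rectangle.
    """

    width: float
    depth: float
    anchors: tuple[tuple[float, float, float], ...] = ()
    zones: Mapping[str, tuple[float, float, float, float]] = field(default_factory=dict)
    stationary_tags: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.width <= 0 or self.depth <= 0:
            raise ValueError("barn dimensions must be positive")
        object.__setattr__(self, "anchors", tuple(tuple(map(float, a)) for a in self.anchors))
        object.__setattr__(self, "zones", dict(self.zones))
        object.__setattr__(self, "stationary_tags", dict(self.stationary_tags))
        object.__setattr__(self, "meta", dict(self.meta))
        for ax, ay, _ in self.anchors:
            if not self._inside(ax, ay):
                raise ValueError(f"anchor ({ax}, {ay}) outside barn")
        for name, (x0, y0, x1, y1) in self.zones.items():
            if not (0 <= x0 <= x1 <= self.width and 0 <= y0 <= y1 <= self.depth):
                raise ValueError(f"zone {name!r} outside barn or degenerate")
        for tag, (tx, ty, _) in self.stationary_tags.items():
            if not self._inside(tx, ty):
                raise ValueError(f"stationary tag {tag!r} at ({tx}, {ty}) outside barn")

    def _inside(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width and 0 <= y <= self.depth

    def contains(self, x, y) -> np.ndarray:
        """Vectorised inside-the-barn test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.depth)

    def wall_distance(self, x, y) -> np.ndarray:
        """Distance from (x, y) to the nearest perimeter wall, metres."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.minimum.reduce([x, self.width - x, y, self.depth - y])

    def stationary_xy(self) -> tuple[list[str], np.ndarray]:
        """Stationary tag ids (sorted) and their (n, 2) ground coordinates."""
        ids = sorted(self.stationary_tags)
        xy = np.array([[self.stationary_tags[i][0], self.stationary_tags[i][1]] for i in ids])
        return ids, xy.reshape(-1, 2)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "depth": self.depth,
            "anchors": [list(a) for a in self.anchors],
            "zones": {k: list(v) for k, v in self.zones.items()},
            "stationary_tags": {k: list(v) for k, v in self.stationary_tags.items()},
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BarnLayout":
        return cls(
            width=float(d["width"]),
            depth=float(d["depth"]),
            anchors=tuple(tuple(map(float, a)) for a in d.get("anchors", ())),
            zones={k: tuple(map(float, v)) for k, v in d.get("zones", {}).items()},
            stationary_tags={k: tuple(map(float, v)) for k, v in d.get("stationary_tags", {}).items()},
            meta=d.get("meta", {}),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BarnLayout":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ParseReport:
    """Row-count conservation record for one parsed position file."""

    n_rows: int
    n_kept: int
    n_duplicates_dropped: int
    per_tag: Mapping[str, int]

    def __post_init__(self):
        if self.n_kept + self.n_duplicates_dropped != self.n_rows:
            raise ValueError("row counts do not conserve")


# ---------------------------------------------------------------------------
# Position tables
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = ("tag_id", "timestamp", "x", "y")


def _parse_timestamps(raw: pd.Series, path, offset: int = 2) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        i = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise RowError(i + offset, f"unparsable timestamp {raw.iloc[i]!r} in {path}")
    return parsed


def read_position_table(
    path: str | Path,
    session: Session | None = None,
    sessions: Mapping[str, Session] | None = None,
) -> tuple[list[TagStream], ParseReport]:
    """Read a position CSV (``tag_id,timestamp,x,y``) into per-tag streams.

    Timestamps are ISO-8601.  If ``session`` (applied to every tag) or
    ``sessions`` (per tag id) is given, it supplies the stream epoch and
    metadata; otherwise a session spanning the observed timestamps is
    inferred per tag.  Duplicate ``(tag_id, timestamp)`` rows keep the first
    occurrence; the drop count is reported.

    Returns the streams (sorted by tag id) and a :class:`ParseReport`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _POSITION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    n_rows = len(df)
    if n_rows == 0:
        return [], ParseReport(0, 0, 0, {})

    ts = _parse_timestamps(df["timestamp"], path)
    coords = {}
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise RowError(i + 2, f"non-numeric {col} value {df[col].iloc[i]!r} in {path}")
        coords[col] = vals.to_numpy()

    work = pd.DataFrame(
        {"tag_id": df["tag_id"].to_numpy(), "ts": ts.to_numpy(), "x": coords["x"], "y": coords["y"]}
    )
    # stable sort keeps original file order among equal (tag, timestamp) rows,
    # so "keep first" is deterministic across reads
    work = work.sort_values(["tag_id", "ts"], kind="stable")
    dup = work.duplicated(["tag_id", "ts"], keep="first")
    n_dropped = int(dup.sum())
    work = work[~dup]

    streams: list[TagStream] = []
    per_tag: dict[str, int] = {}
    for tag, grp in work.groupby("tag_id", sort=True):
        tag = str(tag)
        if sessions is not None:
            if tag not in sessions:
                raise FormatError(f"no session supplied for tag {tag!r}")
            sess = sessions[tag]
        elif session is not None:
            sess = session
        else:
            t0 = grp["ts"].iloc[0].to_pydatetime()
            t1 = grp["ts"].iloc[-1].to_pydatetime() + timedelta(seconds=1)
            sess = Session(start=t0, end=t1)
        epoch = pd.Timestamp(sess.start)
        t = (grp["ts"] - epoch).dt.total_seconds().to_numpy()
        if np.any(t < 0):
            raise FormatError(f"tag {tag!r} has fixes before session start in {path}")
        streams.append(TagStream(tag, t, grp["x"].to_numpy(), grp["y"].to_numpy(), sess))
        per_tag[tag] = len(grp)
    return streams, ParseReport(n_rows, n_rows - n_dropped, n_dropped, per_tag)


def write_position_table(streams: Iterable[TagStream], path: str | Path) -> None:
    """Write streams to a position CSV (timestamps to millisecond precision).

    Synthetic (interpolated) fixes are not written: the file format carries
    measured positions only, so a write/read round trip preserves content.
    """
    frames = []
    for s in streams:
        keep = ~s.synthetic
        epoch = pd.Timestamp(s.session.start)
        ts = epoch + pd.to_timedelta(np.round(s.t[keep] * 1000.0) / 1000.0, unit="s")
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": s.tag_id,
                    "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3],
                    "x": np.char.mod("%.6f", s.x[keep]),
                    "y": np.char.mod("%.6f", s.y[keep]),
                }
            )
        )
    out = pd.concat(frames) if frames else pd.DataFrame(columns=list(_POSITION_COLUMNS))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Observer tables
# ---------------------------------------------------------------------------

_OBSERVER_COLUMNS = ("focal_id", "timestamp", "proximate_tag")


def read_observer_table(
    path: str | Path,
    session: Session | None = None,
    grid: float = 15.0,
    tolerance: float | None = None,
) -> list[ObserverRecord]:
    """Read a focal-observation protocol CSV (``focal_id,timestamp,proximate_tag``).

    Timestamps must fall on the ``grid``-second protocol grid (relative to
    the epoch); with ``tolerance`` set (e.g. 1.0 s) off-grid stamps within
    the tolerance are snapped, otherwise they raise :class:`GridError`.
    Empty/none tokens normalise to ``None``.  Records are sorted by focal id
    and time.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _OBSERVER_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    if len(df) == 0:
        return []
    ts = _parse_timestamps(df["timestamp"], path)
    epoch = pd.Timestamp(session.start) if session is not None else ts.min()
    t = (ts - epoch).dt.total_seconds().to_numpy()

    off = t - grid * np.round(t / grid)
    tol = 0.0 if tolerance is None else float(tolerance)
    bad = np.abs(off) > tol + 1e-9
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise GridError(
            f"line {i + 2}: timestamp {df['timestamp'].iloc[i]!r} is {off[i]:+.3f} s "
            f"off the {grid:g}-s protocol grid"
        )
    t = grid * np.round(t / grid)

    records = []
    for focal, ti, token in zip(df["focal_id"], t, df["proximate_tag"]):
        tag = None if token.strip().lower() in NONE_TOKENS else token.strip()
        records.append(ObserverRecord(str(focal), float(ti), tag))
    records.sort(key=lambda r: (r.focal_id, r.t))
    return records


def write_observer_table(
    records: Sequence[ObserverRecord], path: str | Path, epoch: datetime
) -> None:
    """Write observer records as a protocol CSV with ISO timestamps."""
    base = pd.Timestamp(epoch)
    rows = [
        {
            "focal_id": r.focal_id,
            "timestamp": (base + pd.Timedelta(seconds=r.t)).isoformat(),
            "proximate_tag": r.proximate_tag if r.proximate_tag is not None else "NONE",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_OBSERVER_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Barn preset
# ---------------------------------------------------------------------------


def netluky_layout() -> BarnLayout:
    """The 31 m x 12 m free-stall validation barn, as a preset.

    Six perimeter anchors at 4 m height (four corners plus the two long-wall
    midpoints) and ten stationary reference tags: three on the feeding table
    (~2 m high, out of the animals' reach), three in the cubicle row at the
    end of the barn, two in the mid-barn cubicle area and two by the mid-barn
    water troughs (1-1.5 m high).  Tag coordinates are *nominal*: the source
    installation is documented only as a sketch, so placements here are
    chosen to be consistent with the zone descriptions (corner tags in
    corners, centre tags central) and are flagged as such in ``meta``.
    """
    w, d = 31.0, 12.0
    anchors = (
        (0.0, 0.0, 4.0),
        (15.5, 0.0, 4.0),
        (31.0, 0.0, 4.0),
        (0.0, 12.0, 4.0),
        (15.5, 12.0, 4.0),
        (31.0, 12.0, 4.0),
    )
    zones = {
        "feeding_table": (0.0, 9.8, 31.0, 12.0),
        "feed_alley": (0.0, 7.5, 31.0, 9.8),
        "cubicles_end": (0.0, 0.0, 5.0, 7.0),
        "cubicles_mid": (11.0, 0.0, 21.0, 3.5),
        "water_area": (12.5, 4.5, 19.5, 7.5),
        "cubicles_far": (26.0, 0.0, 31.0, 7.0),
    }
    stationary = {
        # feeding table, ~2 m high; the two outer ones sit in the upper corners
        "8C53": (0.8, 10.8, 2.0),
        "B673": (15.5, 10.8, 2.0),
        "B7AE": (30.2, 10.8, 2.0),
        # end-of-barn cubicle row, 1-1.5 m; A6DA in the lower-left corner
        "A6DA": (0.6, 0.6, 1.2),
        "B21F": (0.8, 4.5, 1.2),
        "B13B": (3.5, 1.0, 1.2),
        # mid-barn cubicle area
        "9578": (13.0, 1.8, 1.2),
        "C4E1": (18.5, 1.8, 1.2),
        # mid-barn water area
        "D512": (14.5, 6.0, 1.0),
        "E9A0": (17.5, 6.0, 1.0),
    }
    return BarnLayout(
        width=w,
        depth=d,
        anchors=anchors,
        zones=zones,
        stationary_tags=stationary,
        meta={"name": "netluky", "tag_coordinates": "nominal"},
    )
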