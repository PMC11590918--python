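"""Trajectory-cleaning operators for UWB position streams.

Three standard repairs for the three characteristic UWB error modes:

* :func:`jump_filter` — drops isolated reflection spikes (fixes far from
  *both* temporal neighbours);
* :func:`median_smooth` — centred running median against Gaussian jitter;
* :func:`interpolate_gaps` — fills short dropouts with linearly
  interpolated whole-second fixes, flagged synthetic so they never count
  toward reliability.

Operators are pure (input streams are never mutated) and composable; order
of application is explicit and up to the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import TagStream

__all__ = ["jump_filter", "median_smooth", "interpolate_gaps", "apply_pipeline"]


def jump_filter(stream: TagStream, min_jump: float = 2.0) -> TagStream:
    """Remove isolated spikes: fixes farther than ``min_jump`` from both neighbours.

    Endpoint fixes are judged by their single neighbour.  A fix is dropped
    only when every neighbour it has is more than ``min_jump`` away, so
    genuine fast traversals (where consecutive fixes move together) are kept.
    """
    n = len(stream)
    if n <= 1:
        return stream.replace()
    dx = np.diff(stream.x)
    dy = np.diff(stream.y)
    step = np.hypot(dx, dy)  # step[i] = distance fix i -> fix i+1
    far_prev = np.concatenate([[False], step > min_jump])
    far_next = np.concatenate([step > min_jump, [False]])
    has_prev = np.arange(n) > 0
    has_next = np.arange(n) < n - 1
    spike = (far_prev | ~has_prev) & (far_next | ~has_next)
    spike &= has_prev | has_next  # single-fix stream never removed
    keep = ~spike
    return TagStream(
        stream.tag_id,
        stream.t[keep],
        stream.x[keep],
        stream.y[keep],
        stream.session,
        stream.synthetic[keep],
    )


def median_smooth(stream: TagStream, window: int = 5) -> TagStream:
    """Centred running median of each coordinate; timestamps unchanged.

    ``window`` must be odd and >= 3; near the stream edges the window
    shrinks symmetrically (keeping the fix centred and the count odd), so
    constant and monotone streams pass through unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd count >= 3")
    n = len(stream)
    if n == 0:
        return stream.replace()
    half = window // 2

    def smooth(v: np.ndarray) -> np.ndarray:
        out = pd.Series(v).rolling(window, center=True).median().to_numpy()
        for i in list(range(min(half, n))) + list(range(max(0, n - half), n)):
            h = min(i, n - 1 - i, half)
            out[i] = np.median(v[i - h : i + h + 1])
        return out

    x = smooth(stream.x)
    y = smooth(stream.y)
    return TagStream(
        stream.tag_id, stream.t.copy(), x, y, stream.session, stream.synthetic.copy()
    )


def interpolate_gaps(stream: TagStream, max_gap: float = 3.0) -> TagStream:
    """Fill short gaps with linearly interpolated whole-second fixes.

    Inside every inter-fix gap of length at most ``max_gap`` seconds, fixes
    are inserted at the whole seconds strictly between the bounding fixes,
    linearly interpolated, and flagged synthetic.  Longer gaps are left
    untouched.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    n = len(stream)
    if n <= 1:
        return stream.replace()
    ts = [stream.t]
    xs = [stream.x]
    ys = [stream.y]
    syn = [stream.synthetic]
    for i in range(n - 1):
        t0, t1 = stream.t[i], stream.t[i + 1]
        gap = t1 - t0
        if gap <= 1.0 or gap > max_gap:
            continue
        new_t = np.arange(np.floor(t0) + 1.0, t1, 1.0)
        new_t = new_t[new_t > t0]
        if new_t.size == 0:
            continue
        frac = (new_t - t0) / gap
        ts.append(new_t)
        xs.append(stream.x[i] + frac * (stream.x[i + 1] - stream.x[i]))
        ys.append(stream.y[i] + frac * (stream.y[i + 1] - stream.y[i]))
        syn.append(np.ones(new_t.size, dtype=bool))
    t = np.concatenate(ts)
    order = np.argsort(t, kind="stable")
    return TagStream(
        stream.tag_id,
        t[order],
        np.concatenate(xs)[order],
        np.concatenate(ys)[order],
        stream.session,
        np.concatenate(syn)[order],
    )


_OPS = {"jump": jump_filter, "median": median_smooth, "interp": interpolate_gaps}


def apply_pipeline(stream: TagStream, spec: str) -> TagStream:
    """Apply a left-to-right operator pipeline given as e.g. ``"jump:2.0,median:5,interp:3"``."""
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        name, _, arg = part.partition(":")
        if name not in _OPS:
            raise ValueError(f"unknown filter {name!r} (choose from {sorted(_OPS)})")
        if name == "median":
            stream = median_smooth(stream, int(arg) if arg else 5)
        elif name == "jump":
            stream = jump_filter(stream, float(arg) if arg else 2.0)
        else:
            stream = interpolate_gaps(stream, float(arg) if arg else 3.0)
    return stream
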