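"""The modified entropy scale (MESC) and sliding estimation windows.

The MESC of order 0 is the RR-interval series itself; the MESC of order n
is the first difference of the order n-1 series, i.e. the n-fold iterated
difference.  It measures beat-to-beat *change*: near zero for a metronomic
rhythm, large and erratic for a disordered one.  Closed form::

    mesc_n[i] = sum_k (-1)^k C(n, k) rr[i + n - k]

Estimation windows are fixed-length runs of consecutive RR intervals
(default 150 beats) addressed by 0-based half-open beat ranges; rhythm
labels are assigned over the window's time span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import RRSeries, RhythmSegment

__all__ = ["MescSeries", "Window", "mesc", "make_windows", "label_windows"]

AMBIGUOUS = "ambiguous"
AF = "AF"
NON_AF = "non-AF"


@dataclass(frozen=True)
class MescSeries:
    """MESC values of a given order; order 0 equals the RR intervals."""

    order: int
    values: np.ndarray
    parent_record: str = ""

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Window:
    """Half-open beat-index range [start_beat, start_beat + length)."""

    start_beat: int
    length: int
    label: str | None = None
    t_start: float = float("nan")
    t_end: float = float("nan")

    @property
    def stop_beat(self) -> int:
        return self.start_beat + self.length


def mesc(rr: RRSeries | np.ndarray, order: int) -> MescSeries:
    """Compute the MESC series of the given order.

    Returns an empty series with a warning when the input is too short
    (length <= order leaves no differences to take).
    """
    if order < 0:
        raise ValueError("MESC order must be non-negative")
    if isinstance(rr, RRSeries):
        values, rid = rr.intervals, rr.record_id
    else:
        values, rid = np.asarray(rr, dtype=float), ""
    if values.size <= order:
        warnings.warn(f"series of length {values.size} too short for MESC order {order}")
        return MescSeries(order=order, values=np.empty(0), parent_record=rid)
    out = np.diff(values, n=order) if order else values.copy()
    return MescSeries(order=order, values=out, parent_record=rid)


def make_windows(rr: RRSeries, window_length: int, stride: int) -> list[Window]:
    """Tile the RR series with overlapping windows; drop the final partial one."""
    if window_length < 2:
        raise ValueError("window_length must be at least 2 beats")
    if not 1 <= stride <= window_length:
        raise ValueError("stride must satisfy 1 <= stride <= window_length")
    n = len(rr)
    if n < window_length:
        return []
    windows = []
    for start in range(0, n - window_length + 1, stride):
        stop = start + window_length
        # interval i spans (timestamps[i] - intervals[i], timestamps[i]]
        t_start = float(rr.timestamps[start] - rr.intervals[start])
        t_end = float(rr.timestamps[stop - 1])
        windows.append(Window(start_beat=start, length=window_length,
                              t_start=t_start, t_end=t_end))
    return windows


def label_windows(windows: list[Window], segments: list[RhythmSegment]) -> list[Window]:
    """Assign AF / non-AF / ambiguous labels by the windows' time spans.

    A window wholly inside AF segments is "AF"; wholly inside non-AF
    segments "non-AF"; one spanning a rhythm boundary (or falling outside
    every annotated segment) is "ambiguous" and is excluded downstream.
    """
    segs = sorted(segments, key=lambda s: s.start)
    out = []
    for w in windows:
        af_cover = _covered(w, segs, af=True)
        non_af_cover = _covered(w, segs, af=False)
        if af_cover and not non_af_cover:
            label = AF
        elif non_af_cover and not af_cover:
            label = NON_AF
        else:
            if not af_cover and not non_af_cover:
                warnings.warn(f"window [{w.t_start:.1f}, {w.t_end:.1f}] s outside all "
                              "rhythm segments; labeled ambiguous")
            label = AMBIGUOUS
        out.append(replace(w, label=label))
    return out


def _covered(w: Window, segs: list[RhythmSegment], af: bool) -> bool:
    """Whether any part of the window's span lies in a segment of the given class."""
    eps = 1e-9  # boundary-touching windows are not "spanning"
    for s in segs:
        if (s.label == AF) == af and s.start < w.t_end - eps and s.end > w.t_start + eps:
            return True
    return False
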