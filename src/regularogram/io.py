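"""Reading beat/rhythm annotations and the package's tabular outputs.

Two input dialects are supported:

* ``csv`` — plain delimited text: beat times in seconds (one per row or
  comma-separated), rhythm segments as ``start,end,label`` rows.
* ``wfdb-annotation`` — the MIT/PhysioNet binary annotation format used by
  the Holter databases (LTAFDB, AFDB, MITDB, NSRDB).  Annotations are
  sample-indexed; a sampling frequency is required and all times are
  converted to seconds here, so sample indices never leak out of this
  module.

Rhythm labels are normalised so that the atrial-fibrillation aux strings
``(AFIB``/``AFIB``/``AF`` all map to the canonical label ``"AF"``.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BeatTimes",
    "RRSeries",
    "RhythmSegment",
    "FormatError",
    "DataError",
    "read_beat_annotations",
    "rr_from_beats",
    "read_rhythm_segments",
    "write_index_table",
    "read_index_table",
    "normalize_rhythm_label",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed under its declared dialect."""


class DataError(ValueError):
    """Raised when parsed data violates a structural invariant."""


@dataclass(frozen=True)
class BeatTimes:
    """Strictly increasing beat occurrence times, in seconds from record start."""

    times: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise DataError("beat times must be one-dimensional")
        if t.size and t[0] < 0:
            raise DataError("beat times must be non-negative")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise DataError(f"beat times not strictly increasing at index {bad[0] + 1}")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class RRSeries:
    """Inter-beat (RR) intervals in seconds.

    ``timestamps[i]`` is the time of the beat that terminates interval ``i``.
    """

    intervals: np.ndarray
    timestamps: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "timestamps", ts)
        if iv.shape != ts.shape:
            raise DataError("intervals and timestamps must have equal length")
        if iv.size and iv.min() <= 0:
            raise DataError("RR intervals must be positive")
        if ts.size > 1 and np.any(np.diff(ts) <= 0):
            raise DataError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class RhythmSegment:
    """A labeled time span, ``[start, end)`` in seconds.

    ``inferred_end`` flags a segment whose end was not annotated explicitly
    but closed at the record end (last beat time).
    """

    start: float
    end: float
    label: str
    inferred_end: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"segment start {self.start} must precede end {self.end}")

    def duration(self) -> float:
        return self.end - self.start


_AF_ALIASES = {"(AFIB", "AFIB", "AF", "(AF"}

#: Rhythm labels recognised without a warning.  Unknown labels are kept
#: verbatim; downstream code only distinguishes "AF" from everything else.
KNOWN_LABELS = {
    "AF", "N", "NSR", "AFL", "B", "BII", "IVR", "NOD", "P", "PREX",
    "SBR", "SVTA", "T", "VFL", "VT", "AB", "J", "PAC", "PVC",
}


def normalize_rhythm_label(label: str) -> str:
    """Map aux-string spellings onto canonical labels ("(AFIB" -> "AF")."""
    label = label.strip().rstrip("\x00")
    if label.upper() in _AF_ALIASES:
        return "AF"
    return label.lstrip("(")


# ---------------------------------------------------------------------------
# MIT/PhysioNet annotation format
#
# The format is a stream of little-endian 16-bit words.  The top 6 bits of
# each word hold an annotation type code, the low 10 bits a time increment
# in samples.  Codes 59-63 are pseudo-annotations (SKIP carries a 4-byte
# interval; NUM/SUB/CHN set modifiers; AUX is followed by a byte-counted,
# even-padded string).  A zero word terminates the stream.
# ---------------------------------------------------------------------------

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
_RHYTHM = 28  # '+' rhythm-change annotation
# Beat codes per the standard annotation code table (NORMAL..RONT plus
# supraventricular/ventricular escapes); excludes non-beat event codes.
_BEAT_CODES = frozenset(range(1, 14)) | {16, 25, 30, 31, 32, 33, 34, 35, 38, 41}


def _parse_mit_annotations(raw: bytes) -> list[tuple[int, int, str | None]]:
    """Decode an MIT annotation byte stream to (sample, code, aux) triples."""
    out: list[tuple[int, int, str | None]] = []
    t = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        word = struct.unpack_from("<H", raw, i)[0]
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            if i + 4 > n:
                raise FormatError("truncated SKIP pseudo-annotation")
            high, low = struct.unpack_from("<HH", raw, i)
            i += 4
            t += (high << 16) | low
        elif code == _AUX:
            if i + delta > n:
                raise FormatError("truncated AUX string")
            aux = raw[i : i + delta].decode("latin-1")
            i += delta + (delta & 1)  # pad to even byte count
            if out:
                sample, prev_code, _ = out[-1]
                out[-1] = (sample, prev_code, aux)
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            t += delta
            out.append((t, code, None))
    return out


def _read_mit_file(path) -> list[tuple[int, int, str | None]]:
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        return _parse_mit_annotations(raw)
    except struct.error as exc:  # pragma: no cover - defensive
        raise FormatError(f"cannot parse {path!s} as an MIT annotation file") from exc


def _parse_number_stream(text: str) -> np.ndarray:
    toks = [tok for tok in text.replace(",", " ").split() if tok]
    try:
        return np.array([float(t) for t in toks], dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric token in beat-time file: {exc}") from exc


def read_beat_annotations(path, dialect: str = "csv", fs: float | None = None,
                          record_id: str | None = None) -> BeatTimes:
    """Read beat occurrence times and return them in seconds, sorted and deduplicated.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {"csv", "wfdb-annotation"}
        ``csv`` expects beat times in seconds, one per row or comma
        separated.  ``wfdb-annotation`` expects an MIT binary annotation
        file with sample-indexed beat marks; ``fs`` (Hz) is then required.
    fs : float, optional
        Sampling frequency for sample-indexed dialects.
    """
    rid = record_id if record_id is not None else str(path)
    if dialect == "csv":
        with open(path, "r", encoding="utf-8") as fh:
            times = _parse_number_stream(fh.read())
    elif dialect == "wfdb-annotation":
        if fs is None or fs <= 0:
            raise ValueError("wfdb-annotation dialect requires a positive sampling frequency fs")
        anns = _read_mit_file(path)
        samples = [s for s, code, _ in anns if code in _BEAT_CODES]
        times = np.asarray(samples, dtype=float) / fs
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    times = np.unique(times)  # sorts and collapses duplicate beat marks
    return BeatTimes(times=times, record_id=rid)


def rr_from_beats(beats: BeatTimes) -> RRSeries:
    """Subtract consecutive beat times to yield the RR-interval series."""
    t = beats.times
    if t.size < 2:
        return RRSeries(intervals=np.empty(0), timestamps=np.empty(0),
                        record_id=beats.record_id)
    return RRSeries(intervals=np.diff(t), timestamps=t[1:], record_id=beats.record_id)


def _segments_from_events(events: list[tuple[float, str]], record_end: float | None,
                          fallback_end: float | None) -> list[RhythmSegment]:
    segments: list[RhythmSegment] = []
    inferred = record_end is None
    end_time = record_end if record_end is not None else fallback_end
    if end_time is None:
        raise DataError("record end time is unknown; supply record_end or beat times")
    for k, (start, label) in enumerate(events):
        stop = events[k + 1][0] if k + 1 < len(events) else end_time
        if stop <= start:
            if k + 1 == len(events):
                break  # rhythm change at/after record end: nothing to close
            raise DataError(f"rhythm events out of order at t={start}")
        segments.append(RhythmSegment(start, stop, label,
                                      inferred_end=inferred and k + 1 == len(events)))
    return segments


def _check_no_overlap(segments: list[RhythmSegment]) -> None:
    ordered = sorted(segments, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise DataError(f"overlapping rhythm segments at t={b.start}")


def read_rhythm_segments(path, dialect: str = "csv", fs: float | None = None,
                         record_end: float | None = None,
                         beats: BeatTimes | None = None) -> list[RhythmSegment]:
    """Read rhythm annotations and return closed, non-overlapping segments.

    CSV rows are either ``start,end,label`` (pre-closed segments) or
    ``time,label`` (rhythm-change events, closed at the next event; the last
    at the record end).  The wfdb dialect reads '+' rhythm-change
    annotations with their aux strings.  When no explicit ``record_end`` is
    given the last segment closes at the final beat time and is flagged
    ``inferred_end``.
    """
    fallback_end = float(beats.times[-1]) if beats is not None and len(beats) else None

    if dialect == "csv":
        events: list[tuple[float, str]] = []
        segments: list[RhythmSegment] = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split(",")]
                try:
                    if len(parts) == 3:
                        segments.append(RhythmSegment(float(parts[0]), float(parts[1]),
                                                      _warned_label(parts[2])))
                    elif len(parts) == 2:
                        events.append((float(parts[0]), _warned_label(parts[1])))
                    else:
                        raise ValueError("expected 2 or 3 comma-separated fields")
                except ValueError as exc:
                    raise FormatError(f"{path!s}:{lineno}: {exc}") from exc
        if segments and events:
            raise FormatError(f"{path!s}: mixed segment and event rows")
        if events:
            segments = _segments_from_events(events, record_end, fallback_end)
    elif dialect == "wfdb-annotation":
        if fs is None or fs <= 0:
            raise ValueError("wfdb-annotation dialect requires a positive sampling frequency fs")
        anns = _read_mit_file(path)
        events = [(s / fs, _warned_label(aux)) for s, code, aux in anns
                  if code == _RHYTHM and aux is not None]
        segments = _segments_from_events(events, record_end, fallback_end)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    _check_no_overlap(segments)
    return segments


def _warned_label(raw: str) -> str:
    label = normalize_rhythm_label(raw)
    if label not in KNOWN_LABELS:
        warnings.warn(f"unknown rhythm label {raw!r} kept verbatim", stacklevel=3)
    return label


# ---------------------------------------------------------------------------
# Index tables
# ---------------------------------------------------------------------------

INDEX_COLUMNS = ["record_id", "window_start_beat", "window_end_beat",
                 "t_start", "t_end", "variability", "normality", "mean_rr", "label"]


def write_index_table(records, path) -> None:
    """Write per-window index records to CSV (schema in ``INDEX_COLUMNS``)."""
    rows = [{
        "record_id": r.record_id,
        "window_start_beat": r.window.start_beat,
        "window_end_beat": r.window.start_beat + r.window.length,
        "t_start": r.window.t_start,
        "t_end": r.window.t_end,
        "variability": r.variability,
        "normality": r.normality,
        "mean_rr": r.mean_rr,
        "label": r.label,
    } for r in records]
    pd.DataFrame(rows, columns=INDEX_COLUMNS).to_csv(path, index=False)


def read_index_table(path):
    """Read an index table written by :func:`write_index_table`."""
    from .indices import WindowIndexRecord
    from .mesc import Window

    try:
        df = pd.read_csv(path, dtype={"record_id": str, "label": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse index table {path!s}: {exc}") from exc
    missing = [c for c in INDEX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"index table {path!s} missing columns: {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        win = Window(start_beat=int(row.window_start_beat),
                     length=int(row.window_end_beat) - int(row.window_start_beat),
                     label=str(row.label), t_start=float(row.t_start),
                     t_end=float(row.t_end))
        records.append(WindowIndexRecord(record_id=str(row.record_id), window=win,
                                         variability=float(row.variability),
                                         normality=float(row.normality),
                                         mean_rr=float(row.mean_rr),
                                         label=str(row.label)))
    return records
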