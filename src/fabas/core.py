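"""Core domain types and I/O for beat-to-beat fetal heart rate data.

The universal input is a :class:`BeatIntervalSeries`: a sequence of
normal-to-normal (NN) beat intervals in milliseconds, each anchored at the
onset time (seconds from recording start) of the beat that opens it, with a
per-interval validity flag. Artifactual intervals are *flagged*, never
deleted, because downstream artifact-fraction rules (e.g. the 50%-artifact
exclusion in the CTG-compatible analysis) need to know how much of the
record is unusable.

All segments and windows in this package use the half-open convention
``[start, end)``; an interval belongs to a window iff its onset time does.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fabas")

#: completed-week gestational age range covered by the methodology
WGA_MIN, WGA_MAX = 21.0, 40.0

SEGMENT_LABELS = ("full30", "quiet", "active", "awake", "unclassified")

#: expected duration (s) per segment label; None = unconstrained
_SEGMENT_DURATION = {"full30": 1800.0, "quiet": 600.0, "active": 600.0, "awake": 600.0}


class FabasError(ValueError):
    """Domain validation error."""


@dataclass(frozen=True)
class SegmentSpec:
    """Half-open time window ``[start, end)`` in seconds with a state label."""

    start: float
    end: float
    label: str = "unclassified"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FabasError(f"segment end {self.end} <= start {self.start}")
        if self.label not in SEGMENT_LABELS:
            raise FabasError(f"unknown segment label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def validate_duration(self, tol: float = 1.0) -> None:
        expected = _SEGMENT_DURATION.get(self.label)
        if expected is not None and abs(self.duration - expected) > tol:
            raise FabasError(
                f"{self.label} segment must span {expected} s, got {self.duration} s"
            )


@dataclass
class BeatIntervalSeries:
    """Validated NN-interval sequence.

    ``beat_times[i]`` is the onset (s) of interval ``i``; ``nn_intervals[i]``
    its duration in ms; ``valid[i]`` whether it is a trustworthy
    normal-to-normal interval. Within a maximal run of valid intervals the
    onset times are consistent with the intervals to 1 ms.
    """

    beat_times: np.ndarray
    nn_intervals: np.ndarray
    valid: np.ndarray
    recording_id: str = ""
    wga: Optional[float] = None
    movement_count: Optional[int] = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.nn_intervals = np.asarray(self.nn_intervals, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.nn_intervals.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.nn_intervals)
        if n == 0:
            raise FabasError("empty interval series")
        if not (len(self.beat_times) == len(self.valid) == n):
            raise FabasError("beat_times, nn_intervals and valid must be equal length")
        dt = np.diff(self.beat_times)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise FabasError(
                f"beat_times not strictly increasing at row {idx + 1} "
                f"(t={self.beat_times[idx + 1]:.4f} after t={self.beat_times[idx]:.4f})"
            )
        # non-positive intervals are demoted to invalid, never dropped
        bad = self.nn_intervals <= 0
        if np.any(bad & self.valid):
            warnings.warn(
                f"{int(np.sum(bad & self.valid))} non-positive NN intervals flagged invalid",
                stacklevel=2,
            )
            self.valid = self.valid & ~bad
        # timing consistency inside valid runs (1 ms tolerance)
        both = self.valid[:-1] & self.valid[1:]
        mismatch = np.abs(dt - self.nn_intervals[:-1] / 1000.0) > 1.5e-3
        if np.any(both & mismatch):
            k = int(np.sum(both & mismatch))
            warnings.warn(
                f"{k} intervals inconsistent with beat times (>1 ms); flagged invalid",
                stacklevel=2,
            )
            drop = np.zeros(n, dtype=bool)
            drop[:-1] |= both & mismatch
            self.valid = self.valid & ~drop
        if self.wga is not None and not (WGA_MIN <= self.wga <= WGA_MAX):
            raise FabasError(f"wga {self.wga} outside [{WGA_MIN}, {WGA_MAX}] weeks")
        if self.movement_count is not None and self.movement_count < 0:
            raise FabasError("movement_count must be non-negative")

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.nn_intervals)

    @property
    def end_times(self) -> np.ndarray:
        """Offset (s) at which each interval closes."""
        return self.beat_times + self.nn_intervals / 1000.0

    @property
    def duration(self) -> float:
        """Recording span in seconds, from first onset to last interval end."""
        return float(self.end_times[-1] - self.beat_times[0])

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    def valid_nn(self) -> np.ndarray:
        return self.nn_intervals[self.valid]

    def valid_times(self) -> np.ndarray:
        return self.beat_times[self.valid]

    def signal_loss_fraction(self) -> float:
        """Fraction of recording *time* not covered by valid intervals."""
        total = self.duration
        covered = float(np.sum(self.nn_intervals[self.valid]) / 1000.0)
        return float(np.clip(1.0 - covered / total, 0.0, 1.0))

    def with_metadata(self, **kw) -> "BeatIntervalSeries":
        return replace(self, **kw)


@dataclass
class InstantaneousHeartRate:
    """Beat-by-beat heart rate (bpm), one value per *valid* interval."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != len(self.times):
            raise FabasError("values/times length mismatch")
        if np.any(self.values <= 0):
            raise FabasError("heart rate must be positive")

    def __len__(self) -> int:
        return len(self.values)


# ----------------------------------------------------------------------
# Operations


def instantaneous_hr(series: BeatIntervalSeries) -> InstantaneousHeartRate:
    """Convert valid NN intervals (ms) to instantaneous heart rate, 60000/NN bpm."""
    if series.n_valid == 0:
        raise FabasError("no valid beats")
    nn = series.valid_nn()
    return InstantaneousHeartRate(values=60000.0 / nn, times=series.valid_times())


def extract_segment(series: BeatIntervalSeries, spec: SegmentSpec) -> BeatIntervalSeries:
    """Return the sub-series whose interval onsets fall in ``[start, end)``.

    Times are re-referenced so the returned series starts at ``t - start``.
    """
    t0 = series.beat_times[0]
    t_end = series.end_times[-1]
    # the recording extent starts at the time reference (0) even when the
    # first detected beat falls shortly after it; a few seconds of slack at
    # the end tolerates a recording ending one beat short of its nominal span
    extent_start = min(0.0, t0)
    if spec.start < extent_start - 1e-9 or spec.end > t_end + 5.0:
        raise FabasError(
            f"segment [{spec.start}, {spec.end}) outside recording "
            f"[{extent_start}, {t_end:.2f})"
        )
    mask = (series.beat_times >= spec.start) & (series.beat_times < spec.end)
    if not np.any(mask):
        raise FabasError("segment contains no beats")
    return BeatIntervalSeries(
        beat_times=series.beat_times[mask] - spec.start,
        nn_intervals=series.nn_intervals[mask],
        valid=series.valid[mask],
        recording_id=series.recording_id,
        wga=series.wga,
        movement_count=series.movement_count,
    )


# ----------------------------------------------------------------------
# I/O


@dataclass(frozen=True)
class CsvDialect:
    """Column layout of interval CSV files.

    Default: comma-separated with header ``time_s,nn_ms,valid``; the valid
    column is optional (missing = all valid).
    """

    delimiter: str = ","
    time_col: str = "time_s"
    nn_col: str = "nn_ms"
    valid_col: str = "valid"
    header: bool = True


DEFAULT_DIALECT = CsvDialect()


def read_interval_series(
    path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    recording_id: str = "",
    wga: Optional[float] = None,
    movement_count: Optional[int] = None,
) -> BeatIntervalSeries:
    """Read a two/three-column beat interval CSV into a validated series.

    Rows violating interval positivity are flagged invalid (with a warning),
    not dropped. Non-monotone beat times are a hard error naming the first
    offending row; an empty file is a hard error.
    """
    if dialect.header:
        df = pd.read_csv(path, sep=dialect.delimiter)
    else:
        names = [dialect.time_col, dialect.nn_col, dialect.valid_col]
        df = pd.read_csv(path, sep=dialect.delimiter, header=None)
        df.columns = names[: df.shape[1]]
    if df.empty:
        raise FabasError(f"empty interval file: {path}")
    for col in (dialect.time_col, dialect.nn_col):
        if col not in df.columns:
            raise FabasError(f"missing column {col!r} in {path}")
    if dialect.valid_col in df.columns:
        valid = df[dialect.valid_col].astype(float).to_numpy() > 0.5
    else:
        valid = np.ones(len(df), dtype=bool)
    series = BeatIntervalSeries(
        beat_times=df[dialect.time_col].to_numpy(dtype=float),
        nn_intervals=df[dialect.nn_col].to_numpy(dtype=float),
        valid=valid,
        recording_id=recording_id or str(path),
        wga=wga,
        movement_count=movement_count,
    )
    flagged = len(series) - series.n_valid
    if flagged:
        logger.info("read %s: %d of %d intervals flagged invalid", path, flagged, len(series))
    return series


def write_interval_series(
    series: BeatIntervalSeries, path, dialect: CsvDialect = DEFAULT_DIALECT
) -> None:
    """Write a series as CSV; lossless round-trip partner of read_interval_series."""
    df = pd.DataFrame(
        {
            dialect.time_col: series.beat_times,
            dialect.nn_col: series.nn_intervals,
            dialect.valid_col: series.valid.astype(int),
        }
    )
    df.to_csv(path, sep=dialect.delimiter, index=False, header=dialect.header,
              float_format="%.9g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def config_fingerprint(settings: dict) -> str:
    """Short stable hash of estimator settings, recorded in every output."""
    import hashlib

    blob = json.dumps(settings, sort_keys=True, default=_json_default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
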