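"""Time-domain heart-rate-variability estimation from R-R interval series.

An R-R tachogram (the sequence of intervals between successive normal
heartbeats, in milliseconds) is segmented into non-overlapping windows of a
fixed number of consecutive beats (256 by default) and the classical
time-domain estimators are computed per window:

* mean R-R interval,
* SDNN — standard deviation of normal-to-normal intervals,
* RMSSD — root mean square of successive interval differences.

Recording-level values are the unweighted mean of the per-window estimators.
The ratio of post-exposure SDNN to pre-exposure SDNN is the response variable
of the downstream regression model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("decostress")

#: Default window width in beats.
DEFAULT_WINDOW_WIDTH = 256

#: Physiologically plausible R-R range (ms); values outside trigger a warning
#: only — no artifact rejection is applied.
PLAUSIBLE_RR_MS = (200.0, 3000.0)

PHASES = ("pre", "post")


@dataclass(frozen=True)
class RRSeries:
    """One recording: an ordered sequence of heart periods in milliseconds."""

    subject_id: str
    phase: str
    intervals: np.ndarray

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if intervals.ndim != 1 or intervals.size < 1:
            raise ValueError("intervals must be a non-empty 1-D sequence")
        if not np.all(intervals > 0):
            raise ValueError("all R-R intervals must be strictly positive")
        lo, hi = PLAUSIBLE_RR_MS
        n_odd = int(np.sum((intervals <= lo) | (intervals >= hi)))
        if n_odd:
            logger.warning(
                "%s/%s: %d interval(s) outside the plausible range (%g, %g) ms",
                self.subject_id, self.phase, n_odd, lo, hi,
            )

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class RRWindow:
    """Exactly ``width`` consecutive R-R intervals from a parent series."""

    intervals: np.ndarray
    window_index: int = 0

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if intervals.ndim != 1 or intervals.size < 2:
            raise ValueError("a window needs at least 2 intervals")
        if not np.all(intervals > 0):
            raise ValueError("all R-R intervals must be strictly positive")

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class TimeDomainFeatures:
    """Time-domain HRV summary of a window or a whole recording."""

    mean_rr: float  # ms
    sdnn: float  # ms
    rmssd: float  # ms
    n_windows: int = 1


def read_rr_series(path: str | Path, subject_id: str, phase: str) -> RRSeries:
    """Read an R-R series from a plain-text file, one interval (ms) per line.

    Lines may also be two comma-separated columns (index, interval); the last
    column is taken as the interval. Blank lines are skipped.

    Raises
    ------
    ValueError
        On a non-numeric line (naming the line number), a non-positive
        interval, or an empty file.
    """
    path = Path(path)
    intervals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            token = line.split(",")[-1].strip()
            try:
                value = float(token)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse {token!r} as an R-R interval"
                ) from None
            if value <= 0:
                raise ValueError(
                    f"{path}:{lineno}: non-positive R-R interval {value!r}"
                )
            intervals.append(value)
    if not intervals:
        raise ValueError(f"{path}: no intervals found")
    return RRSeries(subject_id=subject_id, phase=phase, intervals=np.array(intervals))


def segment_windows(
    series: RRSeries, width: int = DEFAULT_WINDOW_WIDTH
) -> list[RRWindow]:
    """Cut a series into non-overlapping windows of ``width`` consecutive beats.

    Trailing intervals that do not fill a complete window are discarded. A
    series shorter than ``width`` yields an empty list (with a logged warning),
    not an error.
    """
    if width < 2:
        raise ValueError("window width must be >= 2")
    n = len(series) // width
    if n == 0:
        logger.warning(
            "%s/%s: series of %d beats shorter than window width %d; no windows",
            series.subject_id, series.phase, len(series), width,
        )
        return []
    return [
        RRWindow(series.intervals[i * width : (i + 1) * width], window_index=i)
        for i in range(n)
    ]


def time_domain_features(window: RRWindow) -> TimeDomainFeatures:
    """Mean R-R, SDNN (sample sd, N-1 denominator) and RMSSD of one window."""
    x = window.intervals
    diffs = np.diff(x)
    return TimeDomainFeatures(
        mean_rr=float(np.mean(x)),
        sdnn=float(np.std(x, ddof=1)),
        rmssd=float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0,
        n_windows=1,
    )


def summarize_recording(
    features: Sequence[TimeDomainFeatures] | Iterable[TimeDomainFeatures],
) -> TimeDomainFeatures:
    """Unweighted mean of per-window estimators over a whole recording."""
    features = list(features)
    if not features:
        raise ValueError("cannot summarize an empty sequence of windows")
    return TimeDomainFeatures(
        mean_rr=float(np.mean([f.mean_rr for f in features])),
        sdnn=float(np.mean([f.sdnn for f in features])),
        rmssd=float(np.mean([f.rmssd for f in features])),
        n_windows=len(features),
    )


def whole_recording_features(series: RRSeries) -> TimeDomainFeatures:
    """Estimators computed over the entire recording as a single window.

    Alternative aggregation to the default mean-over-windows; exposed because
    either convention is defensible for a 30-minute recording.
    """
    return time_domain_features(RRWindow(series.intervals))


def sdnn_ratio(pre: TimeDomainFeatures, post: TimeDomainFeatures) -> float:
    """Post/pre SDNN ratio — the modeling response variable."""
    if pre.sdnn <= 0:
        raise ValueError("undefined ratio: pre-exposure SDNN is zero")
    return post.sdnn / pre.sdnn
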