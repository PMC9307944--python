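"""Peak-time ingestion, artifact correction, RRI conversion and segmentation.

The processing chain is: raw peak sample indices -> trim trailing zeros ->
rule-based artifact correction on inter-beat intervals -> RR intervals in
milliseconds -> fixed-duration analysis segments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PeakSeries",
    "RRISeries",
    "ArtifactCorrection",
    "ArtifactReport",
    "SegmentSet",
    "InsufficientBeatsError",
    "NonMonotonePeaksError",
    "UncorrectableSeriesError",
    "trim_trailing_zeros",
    "peaks_to_rri",
    "interpolate_rri",
    "correct_artifacts",
    "segment_series",
    "read_peaks_csv",
    "read_peaks_mat",
    # default artifact-correction profiles (interval bounds in seconds)
    "FETAL_BOUNDS",
    "ADULT_BOUNDS",
]

#: plausibility bounds on inter-beat intervals, seconds (fetal: 80-180 bpm)
FETAL_BOUNDS = (0.33, 0.75)
#: adult/maternal profile (40-150 bpm)
ADULT_BOUNDS = (0.4, 1.5)

MIN_INTERPOLATION_RATE = 10.0  # Hz floor for interval-signal resampling


class InsufficientBeatsError(ValueError):
    """Raised when an operation needs more beats than the series holds."""


class NonMonotonePeaksError(ValueError):
    """Raised when peak times are not strictly increasing."""


class UncorrectableSeriesError(ValueError):
    """Raised when the artifact bounds exclude essentially all data."""


@dataclass(frozen=True)
class PeakSeries:
    """Strictly increasing R-peak sample indices with a sampling rate."""

    times: np.ndarray
    sampling_rate: float = 1000.0
    stream_label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times)
        object.__setattr__(self, "times", times)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if times.size and times.min() < 0:
            raise ValueError("peak times must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def times_s(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.times / self.sampling_rate

    @property
    def duration_s(self) -> float:
        """Recording span in seconds, measured to the last peak."""
        return float(self.times[-1]) / self.sampling_rate if len(self) else 0.0


@dataclass(frozen=True)
class RRISeries:
    """Successive inter-beat intervals in milliseconds."""

    intervals: np.ndarray
    t_start: np.ndarray = None  # seconds offset of each interval's onset

    def __post_init__(self):
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if intervals.size and (not np.all(np.isfinite(intervals)) or intervals.min() <= 0):
            raise ValueError("all intervals must be finite and > 0")
        if self.t_start is None:
            t = np.concatenate([[0.0], np.cumsum(intervals[:-1]) / 1000.0])
            object.__setattr__(self, "t_start", t)
        else:
            object.__setattr__(self, "t_start", np.asarray(self.t_start, dtype=float))

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.intervals)) / 1000.0


@dataclass(frozen=True)
class ArtifactCorrection:
    index: int
    kind: str  # too_short | too_long | missed_inserted | extra_merged | ectopic_interpolated
    before_ms: float
    after_ms: float


@dataclass(frozen=True)
class ArtifactReport:
    """Audit trail of one artifact-correction run; serializes losslessly."""

    n_input_beats: int
    corrections: tuple
    interval_min: float
    interval_max: float
    method: str = "rule_based"

    def __len__(self) -> int:
        return len(self.corrections)

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        rows = [
            {
                "SubjectID": subject_id,
                "index": c.index,
                "class": c.kind,
                "before_ms": c.before_ms,
                "after_ms": c.after_ms,
            }
            for c in self.corrections
        ]
        return pd.DataFrame(
            rows, columns=["SubjectID", "index", "class", "before_ms", "after_ms"]
        )


@dataclass(frozen=True)
class SegmentSet:
    """Contiguous near-equal-beat-count analysis windows of one recording."""

    segments: tuple  # of (PeakSeries, RRISeries)
    window_minutes: float
    last_partial: bool

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def trim_trailing_zeros(peaks: PeakSeries) -> PeakSeries:
    """Drop zero-padding at the end of the peak array (leading/interior kept)."""
    times = np.trim_zeros(peaks.times, trim="b")
    if times.size < 2:
        raise InsufficientBeatsError(
            f"only {times.size} peaks remain after trailing-zero trim"
        )
    return replace(peaks, times=times)


def peaks_to_rri(peaks: PeakSeries) -> RRISeries:
    """Convert peak sample indices to inter-beat intervals in milliseconds."""
    if len(peaks) < 2:
        raise InsufficientBeatsError("need >= 2 peaks to form intervals")
    diffs = np.diff(np.asarray(peaks.times, dtype=float))
    if np.any(diffs <= 0):
        raise NonMonotonePeaksError("peak times must be strictly increasing")
    rri = diffs / peaks.sampling_rate * 1000.0
    t_start = np.asarray(peaks.times[:-1], dtype=float) / peaks.sampling_rate
    return RRISeries(rri, t_start=t_start)


def interpolate_rri(
    rri: RRISeries, peaks: PeakSeries, target_rate: float = 4.0
) -> tuple[np.ndarray, float]:
    """Resample the interval series onto a regular grid.

    Interval values are anchored at the second-through-last peak times and
    linearly interpolated between anchors (edges held constant). Rates below
    the floor of 10 Hz are promoted to 10 Hz.

    Returns ``(signal_ms, actual_rate_hz)``.
    """
    if len(peaks) < 3:
        raise InsufficientBeatsError("need >= 3 peaks to interpolate intervals")
    rate = max(float(target_rate), MIN_INTERPOLATION_RATE)
    anchors_s = np.asarray(peaks.times[1:], dtype=float) / peaks.sampling_rate
    n = int(np.rint(anchors_s[-1] * rate))
    x_new = np.arange(n) / rate
    signal = np.interp(x_new, anchors_s, rri.intervals)
    return signal, rate


def _local_median(intervals: np.ndarray, i: int, half_window: int = 5) -> float:
    lo = max(0, i - half_window)
    hi = min(len(intervals), i + half_window + 1)
    return float(np.median(intervals[lo:hi]))


def correct_artifacts(
    peaks: PeakSeries,
    interval_min: float,
    interval_max: float,
    ectopic_tolerance: float = 0.2,
) -> tuple[PeakSeries, ArtifactReport]:
    """Single-pass rule-based correction of implausible inter-beat intervals.

    Rules, applied in order on intervals in seconds:

    1. *ectopic*: an adjacent short/long pair with one member out of bounds
       whose sum is within ``ectopic_tolerance`` of twice the local median is
       replaced by two equal halves of the pair sum.
    2. *extra beat*: an interval below ``interval_min`` is merged with its
       following interval (previous one at the series end).
    3. *missed beat(s)*: an interval above ``interval_max`` is split into
       ``k = round(interval / local median)`` equal parts.

    Total recording duration is conserved by every rule. The pass is
    idempotent: re-running on corrected output yields zero corrections.
    """
    if not 0 < interval_min < interval_max:
        raise ValueError("require 0 < interval_min < interval_max")
    if len(peaks) < 2:
        raise InsufficientBeatsError("need >= 2 peaks")
    iv = np.diff(np.asarray(peaks.times, dtype=float)) / peaks.sampling_rate
    if np.any(iv <= 0):
        raise NonMonotonePeaksError("peak times must be strictly increasing")
    n_input = len(peaks)

    in_range = (iv >= interval_min) & (iv <= interval_max)
    if not np.any(in_range):
        raise UncorrectableSeriesError(
            "artifact bounds exclude every interval in the series"
        )

    corrections: list[ArtifactCorrection] = []
    work = list(iv)

    # pass 1: ectopic short/long pairs
    i = 0
    while i < len(work) - 1:
        a, b = work[i], work[i + 1]
        out = (a < interval_min or a > interval_max or
               b < interval_min or b > interval_max)
        if out and ((a < interval_min) != (b < interval_min)):
            med = _local_median(np.asarray(work), i)
            pair = a + b
            if abs(pair - 2 * med) <= ectopic_tolerance * 2 * med:
                half = pair / 2.0
                if interval_min <= half <= interval_max:
                    corrections.append(
                        ArtifactCorrection(i, "ectopic_interpolated", a * 1000, half * 1000)
                    )
                    corrections.append(
                        ArtifactCorrection(i + 1, "ectopic_interpolated", b * 1000, half * 1000)
                    )
                    work[i] = work[i + 1] = half
                    i += 2
                    continue
        i += 1

    # pass 2: merge too-short intervals with a neighbour
    i = 0
    while i < len(work):
        if work[i] < interval_min:
            if i + 1 < len(work):
                merged = work[i] + work[i + 1]
                corrections.append(
                    ArtifactCorrection(i, "extra_merged", work[i] * 1000, merged * 1000)
                )
                work[i:i + 2] = [merged]
            elif i > 0:
                merged = work[i - 1] + work[i]
                corrections.append(
                    ArtifactCorrection(i, "extra_merged", work[i] * 1000, merged * 1000)
                )
                work[i - 1:i + 1] = [merged]
            else:  # single remaining short interval: nothing to merge with
                raise UncorrectableSeriesError("cannot merge a lone short interval")
        else:
            i += 1

    # pass 3: split too-long intervals (missed beats, or overshoot from merges)
    out: list[float] = []
    for i, v in enumerate(work):
        if v > interval_max:
            med = _local_median(np.asarray(work), i)
            k = int(np.rint(v / med)) if med > 0 else 2
            k = max(k, 2)
            while v / k < interval_min and k > 2:
                k -= 1
            if v / k > interval_max:
                k = int(np.ceil(v / interval_max))
            part = v / k
            if not (interval_min <= part <= interval_max):
                raise UncorrectableSeriesError(
                    f"interval of {v:.3f}s cannot be split within bounds"
                )
            corrections.append(
                ArtifactCorrection(i, "missed_inserted", v * 1000, part * 1000)
            )
            out.extend([part] * k)
        else:
            out.append(v)

    new_iv = np.asarray(out)
    t0 = float(peaks.times[0])
    new_times = t0 + np.concatenate([[0.0], np.cumsum(new_iv)]) * peaks.sampling_rate
    new_times = np.rint(new_times).astype(np.int64)
    report = ArtifactReport(
        n_input_beats=n_input,
        corrections=tuple(corrections),
        interval_min=interval_min,
        interval_max=interval_max,
    )
    return replace(peaks, times=new_times), report


def segment_series(
    peaks: PeakSeries,
    rri: RRISeries,
    window_minutes: float = 5.0,
    n_segments: int | None = None,
) -> SegmentSet:
    """Partition a recording into near-equal-beat-count contiguous windows.

    The segment count is ``max(1, round(duration_s / (60 * window_minutes)))``
    where duration is measured to the last peak. Pass ``n_segments=1`` to
    analyse the whole recording as a single window.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be > 0")
    if len(rri) < 1 or len(peaks) != len(rri) + 1:
        raise ValueError("peaks and rri must describe the same recording")
    duration_s = peaks.duration_s
    if n_segments is None:
        divider = duration_s / (60.0 * window_minutes)
        n_segments = max(1, int(np.rint(divider)))
    idx_chunks = np.array_split(np.arange(len(rri)), n_segments)
    segments = []
    for idx in idx_chunks:
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        seg_peaks = replace(peaks, times=peaks.times[lo:hi + 1])
        seg_rri = RRISeries(rri.intervals[lo:hi], t_start=rri.t_start[lo:hi])
        segments.append((seg_peaks, seg_rri))
    last_partial = segments[-1][1].duration_s < window_minutes * 60.0 - 1e-9
    return SegmentSet(tuple(segments), window_minutes, last_partial)


def read_peaks_csv(
    path_or_buffer, sampling_rate: float = 1000.0, stream_label: str = ""
) -> PeakSeries:
    """Read one column of peak sample indices from delimited text/CSV."""
    df = pd.read_csv(path_or_buffer, header=None, comment="#")
    values = df.iloc[:, 0].to_numpy()
    return PeakSeries(values, sampling_rate=sampling_rate, stream_label=stream_label)


def read_peaks_mat(
    path,
    variable: str,
    row: int = 4,
    sampling_rate: float = 1000.0,
    stream_label: str = "",
) -> PeakSeries:
    """Extract one row of a named variable from a MAT container."""
    from scipy.io import loadmat

    data = loadmat(path)
    if variable not in data:
        raise KeyError(f"variable {variable!r} not found in {path}")
    arr = np.atleast_2d(data[variable])
    return PeakSeries(arr[row], sampling_rate=sampling_rate, stream_label=stream_label)
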