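"""Synthetic RRI generation with known ground truth.

Provides stationary / modulated RRI series, stage-modulated sleep sessions
and beat-level artifact injection so every pipeline stage is testable
without external data. All randomness flows from one seeded generator per
call; modulation is evaluated in beat time (each interval is modulated at
the cumulative onset time of its beat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import PeakSeries, RRISeries

__all__ = [
    "SyntheticSpec",
    "SleepSessionSpec",
    "StageProfile",
    "generate_rri",
    "generate_sleep_session",
    "inject_artifacts",
]

LEGAL_STAGES = (0, 1, 2, 3, 5)


@dataclass(frozen=True)
class SyntheticSpec:
    mean_rri: float = 800.0  # ms
    sd_rri: float = 30.0  # ms
    duration: float = 300.0  # s
    modulation: tuple = ()  # of (freq_hz, amplitude_ms)
    ar1_coeff: float = 0.0
    seed: int = 0
    sampling_rate: float = 1000.0

    def __post_init__(self):
        if self.mean_rri <= 0 or self.duration <= 0:
            raise ValueError("invalid spec: mean_rri and duration must be > 0")
        if not -1 <= self.ar1_coeff <= 1:
            raise ValueError("invalid spec: ar1_coeff must lie in [-1, 1]")
        total_amp = sum(a for _, a in self.modulation)
        if total_amp + 5 * self.sd_rri >= self.mean_rri:
            raise ValueError("invalid spec: amplitudes imply non-positive intervals")


@dataclass(frozen=True)
class StageProfile:
    mean_rri: float = 900.0
    sd_rri: float = 40.0
    hf_amplitude: float = 0.0  # ms of 0.25 Hz modulation


@dataclass(frozen=True)
class SleepSessionSpec:
    schedule: tuple  # of (stage_code, duration_s)
    profiles: dict = field(default_factory=dict)  # stage_code -> StageProfile
    epoch_s: float = 30.0
    seed: int = 0
    sampling_rate: float = 1000.0

    def __post_init__(self):
        if not self.schedule:
            raise ValueError("empty stage schedule")
        for stage, dur in self.schedule:
            if stage not in LEGAL_STAGES:
                raise ValueError(f"illegal stage code {stage}")
            if dur <= 0:
                raise ValueError("schedule durations must be > 0")


def _generate_intervals(rng, mean, sd, duration_s, modulation, ar1, t0=0.0):
    """Sequential beat-time generation: AR(1) noise plus sinusoidal modulation."""
    intervals = []
    t = t0
    e = 0.0
    innov_sd = sd * np.sqrt(1 - ar1 ** 2) if abs(ar1) < 1 else 0.0
    while t - t0 < duration_s:
        e = ar1 * e + innov_sd * rng.standard_normal() if sd > 0 else 0.0
        mod = sum(a * np.sin(2 * np.pi * f * t) for f, a in modulation)
        iv = mean + e + mod
        if iv <= 0:
            raise ValueError("spec produced a non-positive interval")
        intervals.append(iv)
        t += iv / 1000.0
    return np.asarray(intervals), t


def generate_rri(spec: SyntheticSpec) -> tuple[PeakSeries, RRISeries, dict]:
    """Generate a synthetic recording; reproducible under a fixed seed.

    Returns ``(peaks, rri, ground_truth)`` where the truth dict carries the
    generating parameters and exact interval values.
    """
    rng = np.random.default_rng(spec.seed)
    intervals, _ = _generate_intervals(
        rng, spec.mean_rri, spec.sd_rri, spec.duration, spec.modulation, spec.ar1_coeff
    )
    times = np.rint(
        np.concatenate([[0.0], np.cumsum(intervals)]) / 1000.0 * spec.sampling_rate
    ).astype(np.int64)
    peaks = PeakSeries(times, sampling_rate=spec.sampling_rate, stream_label="synthetic")
    rri = RRISeries(np.diff(times) / spec.sampling_rate * 1000.0)
    truth = {
        "spec": spec,
        "intervals_ms": intervals,
        "n_beats": len(times),
    }
    return peaks, rri, truth


def generate_sleep_session(spec: SleepSessionSpec) -> tuple[RRISeries, str, dict]:
    """Concatenated stage-wise RRI plus the matching labeled-sleep file body.

    Label lines are ``"<t> <stage>"`` at ``epoch_s`` spacing in seconds since
    session start. Returns ``(rri, label_text, ground_truth)`` with exact
    per-stage durations in the truth dict.
    """
    rng = np.random.default_rng(spec.seed)
    all_intervals = []
    stage_durations: dict[int, float] = {}
    boundaries = []  # (start_s, end_s, stage)
    t = 0.0
    for stage, duration in spec.schedule:
        profile = spec.profiles.get(stage, StageProfile())
        modulation = ((0.25, profile.hf_amplitude),) if profile.hf_amplitude else ()
        intervals, t_end = _generate_intervals(
            rng, profile.mean_rri, profile.sd_rri, duration, modulation, 0.0, t0=t
        )
        all_intervals.append(intervals)
        boundaries.append((t, t + duration, stage))
        stage_durations[stage] = stage_durations.get(stage, 0.0) + duration
        t += duration
    intervals = np.concatenate(all_intervals)
    rri = RRISeries(intervals)

    lines = []
    total = sum(d for _, d in spec.schedule)
    epoch_t = 0.0
    while epoch_t < total:
        stage = next(s for lo, hi, s in boundaries if lo <= epoch_t < hi)
        lines.append(f"{epoch_t:g} {stage}")
        epoch_t += spec.epoch_s
    label_text = "\n".join(lines) + "\n"
    truth = {"stage_durations": stage_durations, "schedule": spec.schedule}
    return rri, label_text, truth


def inject_artifacts(
    rri: RRISeries, missed_rate: float = 0.0, extra_rate: float = 0.0, seed: int = 0
) -> tuple[RRISeries, list]:
    """Corrupt a series with simulated missed beats (merged interval pairs)
    and extra beats (intervals split asymmetrically).

    Rates are fractions of beats in [0, 0.2]. Returns the corrupted series
    and a truth list of ``(index_in_clean_series, kind)`` entries.
    """
    if not (0 <= missed_rate <= 0.2 and 0 <= extra_rate <= 0.2):
        raise ValueError("rates must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    intervals = list(rri.intervals)
    n = len(intervals)
    n_missed = int(np.floor(missed_rate * n))
    n_extra = int(np.floor(extra_rate * n))
    # choose non-adjacent target indices, applied from the end so earlier
    # indices stay valid
    candidates = rng.permutation(n - 1)
    targets = []
    used: set[int] = set()
    for idx in candidates:
        if len(targets) >= n_missed + n_extra:
            break
        if {idx - 1, idx, idx + 1} & used:
            continue
        used.add(idx)
        targets.append(int(idx))
    truth = []
    kinds = ["missed"] * min(n_missed, len(targets))
    kinds += ["extra"] * (len(targets) - len(kinds))
    for idx, kind in sorted(zip(targets, kinds), reverse=True):
        if kind == "missed":
            merged = intervals[idx] + intervals[idx + 1]
            intervals[idx:idx + 2] = [merged]
        else:
            frac = rng.uniform(0.25, 0.45)
            a = intervals[idx] * frac
            b = intervals[idx] - a
            intervals[idx:idx + 1] = [a, b]
        truth.append((idx, kind))
    truth.reverse()
    return RRISeries(np.asarray(intervals)), truth
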