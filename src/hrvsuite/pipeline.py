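"""Segment-wise metric assembly, batch execution and sleep-stage analysis.

One segment yields one row with the registry's 124 metric columns plus the
quality-control segment duration and the SubjectID. A failure inside any
single metric family leaves those cells missing (logged) and never aborts
the segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import RunConfig, StreamConfig
from .higher_order import summarize_metric_table
from .metrics import complexity as cx
from .metrics.frequency import (
    DEFAULT_BANDS,
    BandDefinition,
    compute_frequency_domain,
    estimate_psd,
)
from .metrics.poincare import compute_asymmetry, compute_fragmentation, compute_poincare
from .metrics.rqa import build_recurrence_plot, compute_rqa
from .metrics.time_domain import compute_time_domain
from .registry import ALL_COLUMNS, METRIC_COLUMNS
from .signal_core import (
    PeakSeries,
    RRISeries,
    correct_artifacts,
    interpolate_rri,
    peaks_to_rri,
    read_peaks_csv,
    read_peaks_mat,
    segment_series,
    trim_trailing_zeros,
)

log = logging.getLogger(__name__)

__all__ = [
    "SleepLabels",
    "CorrelationTable",
    "compute_segment_record",
    "compute_hrv_segmentwise",
    "run_batch",
    "parse_sleep_labels",
    "stage_durations",
    "correlate_metrics_with_stages",
    "write_outputs",
    "bpm_to_rri",
]

LEGAL_STAGES = {0, 1, 2, 3, 5}


@dataclass(frozen=True)
class SleepLabels:
    """Parsed '[id]_labeled_sleep.txt' content: (t_s, stage) per epoch."""

    t: np.ndarray
    stages: np.ndarray
    epoch_s: float


@dataclass(frozen=True)
class CorrelationTable:
    r: pd.DataFrame  # metric summaries x stages
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at p < alpha
    alpha: float = 0.05


def _family(fn, columns, out):
    """Run one metric family, leaving NaNs and a log entry on failure."""
    try:
        out.update(fn())
    except Exception as exc:  # noqa: BLE001 - any single family may fail
        log.warning("metric family %s failed: %s", getattr(fn, "__name__", fn), exc)
        for c in columns:
            out.setdefault(c, np.nan)


def compute_segment_record(
    seg_peaks: PeakSeries,
    seg_rri: RRISeries,
    params: cx.ComplexityParams | None = None,
    bands=DEFAULT_BANDS,
    psd_interp_rate: float = 4.0,
) -> dict[str, float]:
    """All 124 registry metrics plus segment duration for one segment."""
    params = params or cx.ComplexityParams()
    x = seg_rri.intervals
    out: dict[str, float] = {}

    _family(lambda: compute_time_domain(seg_rri), [], out)

    def freq():
        signal, rate = interpolate_rri(seg_rri, seg_peaks, psd_interp_rate)
        freqs, power = estimate_psd(signal, rate)
        return compute_frequency_domain(freqs, power, bands)

    _family(freq, ["ULF", "VLF", "LF", "HF", "VHF", "LFHF", "LFn", "HFn", "LnHF"], out)

    _family(lambda: compute_poincare(seg_rri), [], out)
    _family(lambda: compute_asymmetry(seg_rri), [], out)
    _family(lambda: compute_fragmentation(seg_rri), [], out)

    delay_opt = None
    try:
        delay_opt = cx.estimate_optimal_delay(x, params.delay_max)
    except Exception as exc:  # noqa: BLE001
        log.warning("optimal delay estimation failed: %s", exc)
    if delay_opt is None:
        log.info("optimal delay unavailable; fuzzy pathway downgraded to delay=1")
        out["optimal time delay"] = np.nan
        delay_used = 1
    else:
        mean_nn = float(np.mean(x)) if x.size else np.nan
        out["optimal time delay"] = delay_opt * mean_nn / 1000.0
        delay_used = delay_opt

    _family(lambda: cx.compute_entropy_family(x, params, delay_used), [], out)

    def multiscale():
        res = {}
        for variant in ("MSE", "CMSE", "RCMSE"):
            res[variant], _ = cx.multiscale_entropy(
                x, variant, params.m, params.r, params.scales, delay=1
            )
        for variant in ("FuzzEnMSE", "FuzzEnRCMSE"):
            # segment-specific optimal delay pathway
            safe_delay = delay_used
            if x.size // max(params.scales) <= (params.m + 1) * safe_delay:
                safe_delay = 1
            res[variant], _ = cx.multiscale_entropy(
                x, variant, params.m, params.r, params.scales, delay=safe_delay
            )
        return res

    _family(multiscale, ["MSE", "CMSE", "RCMSE", "FuzzEnMSE", "FuzzEnRCMSE"], out)

    _family(lambda: cx.compute_fractal_family(x, params), [], out)
    _family(lambda: cx.compute_dfa(x, params), ["DFA", "DFA_alpha1", "DFA_alpha2"], out)
    _family(lambda: cx.compute_mfdfa_features(x, params), [], out)

    def rqa():
        delay = delay_used
        m = 3
        if x.size - (m - 1) * delay <= 10:
            delay = 1
        plot = build_recurrence_plot(x, m=m, delay=delay)
        return compute_rqa(plot)

    _family(rqa, [], out)

    out["segment duration, s"] = float(np.sum(x)) / 1000.0
    for c in METRIC_COLUMNS:
        out.setdefault(c, np.nan)
    return out


def compute_hrv_segmentwise(
    peaks: PeakSeries,
    rri: RRISeries,
    subject_id: str,
    window_minutes: float = 5.0,
    whole_recording: bool = False,
    params: cx.ComplexityParams | None = None,
    bands=DEFAULT_BANDS,
    psd_interp_rate: float = 4.0,
) -> pd.DataFrame:
    """One HRVRecord row per segment, columns fixed by the registry."""
    segs = segment_series(
        peaks, rri, window_minutes, n_segments=1 if whole_recording else None
    )
    if len(segs) == 0:
        raise ValueError("zero segments")
    rows = []
    for seg_peaks, seg_rri in segs:
        record = compute_segment_record(
            seg_peaks, seg_rri, params, bands, psd_interp_rate
        )
        record["SubjectID"] = subject_id
        rows.append(record)
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


def bpm_to_rri(bpm: np.ndarray) -> RRISeries:
    """Convert a heart-rate (bpm) series to pseudo RR intervals.

    True beat-to-beat timing is absent from rate-resampled data; the
    conversion 60000/bpm is an approximation for watch-style inputs.
    """
    log.warning(
        "bpm input converted to pseudo-RRI (60000/bpm); "
        "beat-to-beat timing is not preserved"
    )
    bpm = np.asarray(bpm, dtype=float)
    if np.any(bpm <= 0):
        raise ValueError("bpm values must be > 0")
    return RRISeries(60000.0 / bpm)


def _load_stream_file(path, stream: StreamConfig, sampling_rate: float):
    """Read one input file into a PeakSeries according to the stream kind."""
    if stream.input_kind == "peaks_csv":
        return read_peaks_csv(path, sampling_rate, stream.name)
    if stream.input_kind == "peaks_mat":
        return read_peaks_mat(
            path, stream.mat_variable, stream.mat_row, sampling_rate, stream.name
        )
    if stream.input_kind in ("rri_csv", "bpm_csv"):
        values = pd.read_csv(path, header=None, comment="#").iloc[:, 0].to_numpy(float)
        rri = bpm_to_rri(values) if stream.input_kind == "bpm_csv" else RRISeries(values)
        times = np.rint(
            np.concatenate([[0.0], np.cumsum(rri.intervals)]) / 1000.0 * sampling_rate
        ).astype(np.int64)
        return PeakSeries(times, sampling_rate, stream.name)
    raise ValueError(f"unknown input kind {stream.input_kind!r}")


def run_batch(config: RunConfig) -> dict[str, dict[str, Path]]:
    """Process every configured stream and write the output file set.

    With two paired streams the file lists must have equal length; an
    explicit 'unpaired streams' error names the offending side otherwise.
    Returns ``{stream_name: {kind: path}}``.
    """
    if not config.streams:
        raise ValueError("no input streams configured")
    counts = {s.name: len(s.paths) for s in config.streams}
    if len(config.streams) == 2 and len(set(counts.values())) > 1:
        raise ValueError(f"unpaired streams: file counts differ {counts}")
    for s in config.streams:
        if not s.paths:
            raise ValueError(f"no input files for stream {s.name!r}")
        for p in s.paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)

    params = cx.ComplexityParams(**config.complexity)
    bands = (
        tuple(BandDefinition(*b) for b in config.bands) if config.bands else DEFAULT_BANDS
    )
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", config.to_dict())

    outputs: dict[str, dict[str, Path]] = {}
    for stream in config.streams:
        metric_tables, higher_tables, artifact_frames = [], [], []
        for path in stream.paths:
            subject_id = Path(path).stem
            peaks = _load_stream_file(path, stream, config.sampling_rate)
            peaks = trim_trailing_zeros(peaks)
            peaks, report = correct_artifacts(
                peaks, stream.interval_min, stream.interval_max
            )
            rri = peaks_to_rri(peaks)
            table = compute_hrv_segmentwise(
                peaks,
                rri,
                subject_id,
                config.window_minutes,
                config.whole_recording,
                params,
                bands,
                config.psd_interp_rate,
            )
            metric_tables.append(table)
            if len(table) >= 2:
                higher_tables.append(summarize_metric_table(table, subject_id))
            else:
                log.info("subject %s: single segment, higher-order skipped", subject_id)
            artifact_frames.append(report.to_frame(subject_id))
        tables = {
            f"{stream.name}metrics": pd.concat(metric_tables, ignore_index=True),
            f"higher_{stream.name}metrics": (
                pd.concat(higher_tables) if higher_tables else pd.DataFrame()
            ),
            f"{stream.name}_artifacts_log": pd.concat(artifact_frames, ignore_index=True),
        }
        outputs[stream.name] = write_outputs(tables, out_dir, config.write_xlsx)
    return outputs


def write_outputs(
    tables: dict[str, pd.DataFrame], out_dir: Path, write_xlsx: bool = False
) -> dict[str, Path]:
    """Write each table as CSV (12 significant digits; deterministic bytes).

    XLSX copies are optional. Tables are fully assembled before any file is
    touched, so an unwritable path cannot discard computation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        index = not isinstance(table.index, pd.RangeIndex)
        table.to_csv(path, index=index, float_format="%.12g")
        paths[name] = path
        if write_xlsx:
            table.to_excel(out_dir / f"{name}.xlsx", index=index)
    return paths


# ---------------------------------------------------------------------------
# sleep-stage validation layer


def parse_sleep_labels(content: str) -> SleepLabels:
    """Parse labeled-sleep text: each line is 't_seconds stage' (stages 0-3, 5)."""
    t_vals, stages = [], []
    for lineno, line in enumerate(content.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 't stage', got {line!r}")
        try:
            t = float(parts[0])
            stage = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric entry in {line!r}") from exc
        if stage not in LEGAL_STAGES:
            raise ValueError(f"line {lineno}: illegal stage code {stage}")
        t_vals.append(t)
        stages.append(stage)
    if not t_vals:
        raise ValueError("no label lines found")
    t = np.asarray(t_vals)
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be non-decreasing")
    diffs = np.diff(t)
    epoch = float(pd.Series(diffs).mode().iloc[0]) if diffs.size else np.nan
    return SleepLabels(t=t, stages=np.asarray(stages), epoch_s=epoch)


def stage_durations(labels: SleepLabels) -> dict[int, float]:
    """Total seconds per stage: epoch count times the inferred epoch length."""
    out: dict[int, float] = {}
    for stage in LEGAL_STAGES:
        n = int(np.sum(labels.stages == stage))
        if n:
            out[stage] = n * labels.epoch_s
    return out


def correlate_metrics_with_stages(
    summaries: pd.DataFrame,
    durations: pd.DataFrame,
    alpha: float = 0.05,
) -> CorrelationTable:
    """Spearman R and p for every (metric summary, stage duration) pair.

    ``summaries``: one row per subject, columns are metric summaries (e.g.
    'CV RMSSD'); ``durations``: one row per subject, columns are stage
    codes. No multiple-testing correction (raw p < alpha mask), matching
    the source analysis; constant columns yield missing cells.
    """
    common = summaries.index.intersection(durations.index)
    if len(common) < 5:
        raise ValueError("need >= 5 subjects with both summaries and durations")
    summaries = summaries.loc[common]
    durations = durations.loc[common]
    r = pd.DataFrame(index=summaries.columns, columns=durations.columns, dtype=float)
    p = pd.DataFrame(index=summaries.columns, columns=durations.columns, dtype=float)
    for metric in summaries.columns:
        mvals = summaries[metric].to_numpy(dtype=float)
        for stage in durations.columns:
            svals = durations[stage].to_numpy(dtype=float)
            ok = np.isfinite(mvals) & np.isfinite(svals)
            if ok.sum() < 5 or np.ptp(mvals[ok]) == 0 or np.ptp(svals[ok]) == 0:
                log.info("correlation cell (%s, %s) skipped", metric, stage)
                continue
            res = spearmanr(mvals[ok], svals[ok])
            r.loc[metric, stage] = res.statistic
            p.loc[metric, stage] = res.pvalue
    significant = (p < alpha) & p.notna()
    return CorrelationTable(r=r, p=p, significant=significant, alpha=alpha)
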