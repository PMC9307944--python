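"""Run configuration for batch processing, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .signal_core import ADULT_BOUNDS

__all__ = ["StreamConfig", "RunConfig", "load_config"]


@dataclass
class StreamConfig:
    """One input stream (e.g. 'fetal' or 'maternal')."""

    name: str
    paths: list = field(default_factory=list)
    interval_min: float = ADULT_BOUNDS[0]
    interval_max: float = ADULT_BOUNDS[1]
    input_kind: str = "peaks_csv"  # peaks_csv | rri_csv | bpm_csv | peaks_mat
    mat_variable: str = ""
    mat_row: int = 4


@dataclass
class RunConfig:
    streams: list = field(default_factory=list)  # of StreamConfig
    sampling_rate: float = 1000.0
    window_minutes: float = 5.0
    whole_recording: bool = False  # divider = 1 mode
    output_dir: str = "analysis"
    write_xlsx: bool = False
    hmm_enabled: bool = False
    psd_interp_rate: float = 4.0
    seed: int = 0
    complexity: dict = field(default_factory=dict)  # ComplexityParams overrides
    bands: list = field(default_factory=list)  # optional [name, lo, hi] triples

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    streams = [StreamConfig(**s) for s in raw.pop("streams", [])]
    cfg = RunConfig(streams=streams, **raw)
    return cfg
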