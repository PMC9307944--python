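"""The version-locked 124-column metric registry.

Column names and order define the per-segment output row. Changing this
list is a breaking change guarded by tests. The quality-control column
("segment duration, s") and SubjectID are appended after the metrics and
are not part of the 124.
"""

from __future__ import annotations

from .metrics.frequency import FREQUENCY_COLUMNS
from .metrics.poincare import ASYMMETRY_COLUMNS, FRAGMENTATION_COLUMNS, POINCARE_COLUMNS
from .metrics.rqa import RQA_COLUMNS
from .metrics.time_domain import TIME_DOMAIN_COLUMNS

__all__ = ["METRIC_COLUMNS", "QC_COLUMNS", "ALL_COLUMNS", "METRIC_FAMILIES"]

COMPLEXITY_COLUMNS = [
    "ApEn", "SampEn", "MSE", "CMSE", "RCMSE", "DFA", "CorrDim",
    "optimal time delay",
    "FuzzEn", "FuzzEnMSE", "FuzzEnRCMSE", "cApEn",
    "CREn", "DiffEn", "FI", "Hjorth", "Hurst", "KFD", "LZC", "MSPEn",
    "NLD", "PEn", "PFD", "PLZC", "PSDslope", "RR", "SDA", "SFD",
    "SVDEn", "SpEn", "WPEn", "ShanEn", "HFD",
]

MFDFA_FEATURES = [
    "Width", "Peak", "Mean", "Max", "Delta", "Asymmetry", "Fluctuation", "Increment"
]

DFA_MFDFA_COLUMNS = (
    ["DFA_alpha1"]
    + [f"MFDFA_alpha1_{k}" for k in MFDFA_FEATURES]
    + ["DFA_alpha2"]
    + [f"MFDFA_alpha2_{k}" for k in MFDFA_FEATURES]
)

METRIC_FAMILIES = {
    "time": TIME_DOMAIN_COLUMNS,
    "frequency": FREQUENCY_COLUMNS,
    "rqa": RQA_COLUMNS,
    "poincare": POINCARE_COLUMNS,
    "fragmentation": FRAGMENTATION_COLUMNS,
    "asymmetry": ASYMMETRY_COLUMNS,
    "complexity": COMPLEXITY_COLUMNS,
    "dfa_mfdfa": DFA_MFDFA_COLUMNS,
}

METRIC_COLUMNS: list[str] = [c for cols in METRIC_FAMILIES.values() for c in cols]

QC_COLUMNS = ["segment duration, s"]
ALL_COLUMNS = METRIC_COLUMNS + QC_COLUMNS + ["SubjectID"]
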