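"""Second estimation layer: fluctuation statistics of per-segment metrics.

Each HRV metric's across-segment time series is summarized by its mean,
coefficient of variation (population SD / mean), quartile coefficient of
dispersion and a binned Shannon entropy; an optional Gaussian hidden Markov
state model is available for longer metric series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "BASIC_STAT_COLUMNS",
    "compute_basic_stats",
    "fit_state_model",
    "summarize_metric_table",
    "StateSequence",
    "DegenerateStateModelError",
]

BASIC_STAT_COLUMNS = [
    "SubjectID", "mean", "coeff_variation",
    "quartile_coefficient_dispersion", "HRV metrics entropy",
]


class DegenerateStateModelError(ValueError):
    """Raised when a state model is requested for a constant series."""


@dataclass(frozen=True)
class StateSequence:
    states: np.ndarray
    n_states: int
    means: np.ndarray
    variances: np.ndarray


def metric_series_entropy(values: np.ndarray, bins: int | None = None) -> float:
    """Shannon entropy (bits) of the metric series binned into ceil(sqrt(n))
    equal-width bins; zero for constant series."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0
    if bins is None:
        bins = max(1, int(np.ceil(np.sqrt(x.size))))
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def compute_basic_stats(metric_series, subject_id: str) -> dict:
    """Mean, CV, quartile coefficient of dispersion and binned entropy.

    CV uses the population SD (ddof=0). Q1/Q3 use midpoint interpolation;
    QCD = (IQR/2) / midhinge with midhinge = (Q3 + Q1)/2. Division-by-zero
    cases yield NaN with a log entry, never an exception.
    """
    x = np.asarray(metric_series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 finite values")
    mean = float(np.mean(x))
    if mean != 0:
        cv = float(np.std(x) / mean)
    else:
        cv = np.nan
        log.info("CV undefined (mean = 0) for subject %s", subject_id)
    q1 = float(np.percentile(x, 25, method="midpoint"))
    q3 = float(np.percentile(x, 75, method="midpoint"))
    iqr = q3 - q1
    midhinge = (q3 + q1) / 2.0
    if midhinge != 0:
        qcd = (iqr / 2.0) / midhinge
    else:
        qcd = np.nan
        log.info("QCD undefined (midhinge = 0) for subject %s", subject_id)
    return {
        "SubjectID": subject_id,
        "mean": mean,
        "coeff_variation": cv,
        "quartile_coefficient_dispersion": qcd,
        "HRV metrics entropy": metric_series_entropy(x),
    }


def fit_state_model(metric_series, n_states: int = 2, seed: int = 0) -> StateSequence:
    """Fit a Gaussian hidden Markov model to one metric's segment series.

    Experimental (disabled by default in batch runs): short metric series
    make the fit unstable, so a minimum of ``5 * n_states`` points is
    enforced. State labels are permutation-equivalent.
    """
    from hmmlearn import hmm

    x = np.asarray(metric_series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5 * n_states:
        raise ValueError(
            f"need >= {5 * n_states} points for a {n_states}-state model, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateStateModelError("constant series admits no state model")
    model = hmm.GaussianHMM(n_components=n_states, random_state=seed, n_iter=100)
    model.fit(x.reshape(-1, 1))
    states = model.predict(x.reshape(-1, 1))
    return StateSequence(
        states=states,
        n_states=n_states,
        means=model.means_.ravel(),
        variances=model.covars_.ravel(),
    )


def summarize_metric_table(segment_table: pd.DataFrame, subject_id: str) -> pd.DataFrame:
    """One higher-order row per numeric metric column of a segment table.

    Non-numeric columns (e.g. the subject id) and all-missing columns are
    skipped with a log entry. The output is transposed so metrics index the
    rows, with the summary statistics as columns.
    """
    if len(segment_table) < 2:
        raise ValueError("need >= 2 segment rows; run on a longer recording")
    rows = {}
    skipped = []
    for col in segment_table.columns:
        series = segment_table[col]
        if not pd.api.types.is_numeric_dtype(series):
            skipped.append((col, "non-numeric"))
            continue
        values = series.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size < 2:
            skipped.append((col, "all-missing"))
            continue
        stats = compute_basic_stats(finite, subject_id)
        stats.pop("SubjectID")
        rows[col] = stats
    for col, reason in skipped:
        log.info("higher-order summary skipped column %r (%s)", col, reason)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.insert(0, "SubjectID", subject_id)
    return out
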