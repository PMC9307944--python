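"""Time-domain HRV metrics computed on one RRI segment.

All interval statistics are in milliseconds unless the name implies a ratio
(CVNN, CVSD, MCVNN, HTI) or a percentage (pNN50, pNN20). Standard deviations
use ddof=1 (sample SD). Percentiles use midpoint interpolation.
"""

from __future__ import annotations

import numpy as np

from ..signal_core import RRISeries

__all__ = ["compute_time_domain", "TIME_DOMAIN_COLUMNS", "HIST_BIN_WIDTH_MS"]

#: conventional geometric-HRV histogram bin width: 1/128 s
HIST_BIN_WIDTH_MS = 1000.0 / 128.0

TIME_DOMAIN_COLUMNS = [
    "RMSSD", "MeanNN", "SDNN", "SDSD", "CVNN", "CVSD", "MedianNN", "MadNN",
    "MCVNN", "IQRNN", "pNN50", "pNN20", "TINN", "HTI",
    "SDANN1", "SDANN2", "SDANN5", "SDNNI1", "SDNNI2", "SDNNI5",
    "Prc20NN", "Prc80NN", "MinNN", "MaxNN",
]


def _histogram(rri: np.ndarray, bin_width: float):
    lo = np.floor(rri.min() / bin_width) * bin_width
    hi = np.ceil(rri.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(rri, bins=edges)
    return counts, edges


def _tinn(counts: np.ndarray, edges: np.ndarray) -> float:
    """Least-squares triangular baseline width of the interval histogram.

    The triangle is zero outside [N, M], rises linearly to the histogram
    peak and falls linearly back; N and M are chosen to minimise the squared
    error against the histogram. TINN = M - N in ms.
    """
    k = int(np.argmax(counts))
    y = counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak_x, peak_y = centers[k], y[k]
    best = (np.inf, 0.0)
    for n_i in range(0, k + 1):
        for m_i in range(k, len(centers)):
            q = np.zeros_like(y)
            if k > n_i:
                left = slice(n_i, k + 1)
                q[left] = peak_y * (centers[left] - centers[n_i]) / (peak_x - centers[n_i])
            else:
                q[k] = peak_y
            if m_i > k:
                right = slice(k, m_i + 1)
                q[right] = peak_y * (centers[m_i] - centers[right]) / (centers[m_i] - peak_x)
            q[k] = peak_y
            err = float(np.sum((y - q) ** 2))
            if err < best[0]:
                best = (err, centers[m_i] - centers[n_i])
    return best[1]


def _subsegment_stats(rri: np.ndarray, t_start: np.ndarray, minutes: float):
    """SDANN/SDNNI over full n-minute sub-segments; NaN when < 2 of them."""
    width = minutes * 60.0
    t_end = t_start + rri / 1000.0
    total = t_end[-1]
    n_full = int(np.floor(total / width))
    if n_full < 2:
        return np.nan, np.nan
    means, sds = [], []
    for j in range(n_full):
        mask = (t_start >= j * width) & (t_start < (j + 1) * width)
        chunk = rri[mask]
        if chunk.size < 2:
            continue
        means.append(chunk.mean())
        sds.append(chunk.std(ddof=1))
    if len(means) < 2:
        return np.nan, np.nan
    return float(np.std(means, ddof=1)), float(np.mean(sds))


def compute_time_domain(
    rri: RRISeries, bin_width_ms: float = HIST_BIN_WIDTH_MS
) -> dict[str, float]:
    """Compute the full time-domain record for one segment.

    Returns a dict keyed by :data:`TIME_DOMAIN_COLUMNS`; all values NaN when
    fewer than 2 intervals are available.
    """
    x = rri.intervals
    out = {c: np.nan for c in TIME_DOMAIN_COLUMNS}
    if x.size < 2:
        return out
    d = np.diff(x)

    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    median_nn = float(np.median(x))
    mad_nn = float(np.median(np.abs(x - median_nn)))

    out["MeanNN"] = mean_nn
    out["SDNN"] = sdnn
    out["CVNN"] = sdnn / mean_nn if mean_nn else np.nan
    out["MedianNN"] = median_nn
    out["MadNN"] = mad_nn
    out["MCVNN"] = mad_nn / median_nn if median_nn else np.nan
    q25 = float(np.percentile(x, 25, method="midpoint"))
    q75 = float(np.percentile(x, 75, method="midpoint"))
    out["IQRNN"] = q75 - q25
    out["Prc20NN"] = float(np.percentile(x, 20, method="midpoint"))
    out["Prc80NN"] = float(np.percentile(x, 80, method="midpoint"))
    out["MinNN"] = float(np.min(x))
    out["MaxNN"] = float(np.max(x))

    if d.size >= 1:
        rmssd = float(np.sqrt(np.mean(d ** 2)))
        out["RMSSD"] = rmssd
        out["CVSD"] = rmssd / mean_nn if mean_nn else np.nan
        out["pNN50"] = 100.0 * float(np.sum(np.abs(d) > 50.0)) / d.size
        out["pNN20"] = 100.0 * float(np.sum(np.abs(d) > 20.0)) / d.size
    if d.size >= 2:
        out["SDSD"] = float(np.std(d, ddof=1))

    counts, edges = _histogram(x, bin_width_ms)
    out["HTI"] = x.size / float(counts.max())
    out["TINN"] = _tinn(counts, edges)

    for minutes in (1, 2, 5):
        sdann, sdnni = _subsegment_stats(x, rri.t_start - rri.t_start[0], minutes)
        out[f"SDANN{minutes}"] = sdann
        out[f"SDNNI{minutes}"] = sdnni
    return out
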