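"""Spectral decomposition of the interpolated RRI signal into band powers.

Band powers are integrals of a Welch PSD over the conventional HRV bands.
The paper-facing record carries absolute powers (ms^2), the LF/HF ratio,
normalized LF/HF fractions and log-transformed HF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "FREQUENCY_COLUMNS",
    "estimate_psd",
    "compute_frequency_domain",
]

FREQUENCY_COLUMNS = ["ULF", "VLF", "LF", "HF", "VHF", "LFHF", "LFn", "HFn", "LnHF"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 <= self.lo < self.hi:
            raise ValueError("require 0 <= lo < hi")


DEFAULT_BANDS = (
    BandDefinition("ULF", 0.0, 0.0033),
    BandDefinition("VLF", 0.0033, 0.04),
    BandDefinition("LF", 0.04, 0.15),
    BandDefinition("HF", 0.15, 0.4),
    BandDefinition("VHF", 0.4, 0.5),
)


def estimate_psd(
    signal: np.ndarray, sampling_rate: float = 4.0, nperseg: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of a uniformly sampled interval signal.

    Mean-removed, Hann window, 50% overlap. The PSD integral approximates
    the signal variance (Parseval). Returns ``(freqs_hz, power)``.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 64:
        raise ValueError("insufficient data for PSD (need >= 64 samples)")
    if nperseg is None:
        nperseg = min(x.size, 512)
    freqs, power = sps.welch(
        x - x.mean(),
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return freqs, power


def compute_frequency_domain(
    freqs: np.ndarray,
    power: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> dict[str, float]:
    """Integrate the PSD over each band and derive ratio/normalized powers.

    Band power is the rectangle-rule integral over [lo, hi); the normalized
    powers use the total over all configured bands as denominator, so band
    powers sum exactly to the total by construction.
    """
    freqs = np.asarray(freqs)
    power = np.asarray(power)
    if freqs.size < 2:
        raise ValueError("PSD grid too small")
    df = float(freqs[1] - freqs[0])
    out = {c: np.nan for c in FREQUENCY_COLUMNS}
    total = 0.0
    for band in bands:
        mask = (freqs >= band.lo) & (freqs < band.hi)
        p = float(np.sum(power[mask]) * df)
        out[band.name] = p
        total += p
    lf, hf = out.get("LF", np.nan), out.get("HF", np.nan)
    if total > 0:
        out["LFn"] = lf / total
        out["HFn"] = hf / total
    if hf > 0:
        out["LFHF"] = lf / hf
        out["LnHF"] = float(np.log(hf))
    return out
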