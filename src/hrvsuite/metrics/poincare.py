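"""Poincare-plot geometry, heart-rate asymmetry and fragmentation indices.

Conventions (documented, since the source table assumes them):

* Points above the line of identity (LI), i.e. ``RR[n+1] > RR[n]``, are
  heart-rate *decelerations*; points below are *accelerations*.
* ``SD1`` is the uncentered RMS of the perpendicular distances to LI so the
  exact identity ``SD1 = RMSSD / sqrt(2)`` holds on every segment.
* Asymmetry variance partitions follow the short-term/long-term/total
  decomposition with on-LI points splitting their long-term contribution
  equally between decelerations and accelerations, so the contribution
  pairs sum exactly to one.
* Zero successive differences are excluded from fragmentation run
  accounting (neither acceleration nor deceleration).
"""

from __future__ import annotations

import numpy as np

from ..signal_core import RRISeries

__all__ = [
    "compute_poincare",
    "compute_asymmetry",
    "compute_fragmentation",
    "POINCARE_COLUMNS",
    "ASYMMETRY_COLUMNS",
    "FRAGMENTATION_COLUMNS",
]

POINCARE_COLUMNS = ["SD1", "SD2", "SD1SD2", "S", "CSI", "CVI", "CSI_Modified"]
ASYMMETRY_COLUMNS = [
    "GI", "SI", "AI", "PI",
    "C1d", "C1a", "SD1d", "SD1a",
    "C2d", "C2a", "SD2d", "SD2a",
    "Cd", "Ca", "SDNNd", "SDNNa",
]
FRAGMENTATION_COLUMNS = ["PIP", "IALS", "PSS", "PAS"]


def _cloud(rri: RRISeries):
    v = rri.intervals
    return v[:-1], v[1:]


def compute_poincare(rri: RRISeries) -> dict[str, float]:
    """SD1/SD2 ellipse geometry and the derived vagal/sympathetic indices."""
    out = {c: np.nan for c in POINCARE_COLUMNS}
    if len(rri) < 3:
        return out
    x, y = _cloud(rri)
    d = (y - x) / np.sqrt(2.0)
    s = (y + x) / np.sqrt(2.0)
    sd1 = float(np.sqrt(np.mean(d ** 2)))  # uncentered: exactly RMSSD/sqrt(2)
    sd2 = float(np.std(s, ddof=1))
    out["SD1"] = sd1
    out["SD2"] = sd2
    out["S"] = float(np.pi * sd1 * sd2)
    if sd2 > 0:
        out["SD1SD2"] = sd1 / sd2
    if sd1 > 0:
        out["CSI"] = (4 * sd2) / (4 * sd1)
        out["CSI_Modified"] = (4 * sd2) ** 2 / (4 * sd1)
    if sd1 > 0 and sd2 > 0:
        out["CVI"] = float(np.log10(16 * sd1 * sd2))
    return out


def compute_asymmetry(rri: RRISeries) -> dict[str, float]:
    """Guzik/Porta-style asymmetry ratios and the variance partitions."""
    out = {c: np.nan for c in ASYMMETRY_COLUMNS}
    if len(rri) < 3:
        return out
    x, y = _cloud(rri)
    n = x.size
    d = (y - x) / np.sqrt(2.0)  # signed distance to LI; > 0 means deceleration
    dec = d > 0
    acc = d < 0
    on_li = d == 0
    off = ~on_li

    if np.any(off):
        absd = np.abs(d)
        out["GI"] = 100.0 * float(absd[dec].sum() / absd[off].sum())
        theta = np.abs(np.degrees(np.arctan2(y, x)) - 45.0)
        out["SI"] = 100.0 * float(theta[dec].sum() / theta[off].sum()) if theta[off].sum() > 0 else np.nan
        r2 = x ** 2 + y ** 2
        sector = r2 * np.radians(theta) / 2.0
        out["AI"] = 100.0 * float(sector[dec].sum() / sector[off].sum()) if sector[off].sum() > 0 else np.nan
        out["PI"] = 100.0 * float(acc.sum() / off.sum())

    # short-term partition: SD1d^2 + SD1a^2 = SD1^2 exactly
    sd1_sq = float(np.mean(d ** 2))
    sd1d_sq = float(np.sum(d[dec] ** 2) / n)
    sd1a_sq = float(np.sum(d[acc] ** 2) / n)
    out["SD1d"] = np.sqrt(sd1d_sq)
    out["SD1a"] = np.sqrt(sd1a_sq)
    if sd1_sq > 0:
        out["C1d"] = sd1d_sq / sd1_sq
        out["C1a"] = sd1a_sq / sd1_sq

    # long-term partition: on-LI points split equally between the two classes
    s = (y + x - np.mean(x) - np.mean(y)) / np.sqrt(2.0)
    sd2_sq = float(np.mean(s ** 2))
    sd2d_sq = float((np.sum(s[dec] ** 2) + 0.5 * np.sum(s[on_li] ** 2)) / n)
    sd2a_sq = float((np.sum(s[acc] ** 2) + 0.5 * np.sum(s[on_li] ** 2)) / n)
    out["SD2d"] = np.sqrt(sd2d_sq)
    out["SD2a"] = np.sqrt(sd2a_sq)
    if sd2_sq > 0:
        out["C2d"] = sd2d_sq / sd2_sq
        out["C2a"] = sd2a_sq / sd2_sq

    sdnnd_sq = 0.5 * (sd1d_sq + sd2d_sq)
    sdnna_sq = 0.5 * (sd1a_sq + sd2a_sq)
    total = 0.5 * (sd1_sq + sd2_sq)
    out["SDNNd"] = np.sqrt(sdnnd_sq)
    out["SDNNa"] = np.sqrt(sdnna_sq)
    if total > 0:
        out["Cd"] = sdnnd_sq / total
        out["Ca"] = sdnna_sq / total
    return out


def _runs(signs: np.ndarray) -> list[int]:
    """Lengths of maximal constant-sign runs."""
    if signs.size == 0:
        return []
    change = np.where(np.diff(signs) != 0)[0]
    bounds = np.concatenate([[-1], change, [signs.size - 1]])
    return list(np.diff(bounds))


def compute_fragmentation(rri: RRISeries) -> dict[str, float]:
    """Inflection/run statistics of the sign sequence of successive differences."""
    out = {c: np.nan for c in FRAGMENTATION_COLUMNS}
    if len(rri) < 4:
        return out
    d = np.diff(rri.intervals)
    signs = np.sign(d)
    nz = signs[signs != 0]
    if nz.size == 0:
        return out

    inflections = int(np.sum(np.diff(nz) != 0))
    out["PIP"] = 100.0 * inflections / d.size

    run_lengths = _runs(nz)
    mean_run = float(np.mean(run_lengths))
    out["IALS"] = 1.0 / mean_run if mean_run > 0 else np.nan
    short = sum(r for r in run_lengths if r < 3)
    out["PSS"] = 100.0 * short / nz.size

    # alternation segments: maximal stretches of strictly alternating signs
    alt_lengths: list[int] = []
    cur = 1
    for i in range(1, nz.size):
        if nz[i] != nz[i - 1]:
            cur += 1
        else:
            alt_lengths.append(cur)
            cur = 1
    alt_lengths.append(cur)
    in_alt = sum(r for r in alt_lengths if r >= 4)
    out["PAS"] = 100.0 * in_alt / nz.size
    return out
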