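"""Recurrence-plot construction and recurrence quantification measures.

The recurrence matrix is built by delay-embedding the series, thresholding
pairwise Euclidean distances at a fixed fraction of the maximum distance,
and excluding a Theiler band around the main diagonal from all recurrence
counting. Diagonal and vertical structures are scanned from the
Theiler-masked matrix; white vertical lines are scanned with the main
diagonal forced recurrent so trivial self-recurrence never counts as a gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["RecurrencePlot", "build_recurrence_plot", "compute_rqa", "RQA_COLUMNS"]

RQA_COLUMNS = [
    "RecurrenceRate", "Determinism", "DeteRecRatio", "L", "Divergence", "LEn",
    "Laminarity", "TrappingTime", "VMax", "VEn", "W", "WMax", "WEn",
]


class DegeneratePhaseSpaceError(ValueError):
    """Raised when the embedded cloud has zero extent (constant series)."""


@dataclass(frozen=True)
class RecurrencePlot:
    matrix: np.ndarray  # symmetric boolean N x N
    m: int
    delay: int
    radius: float
    theiler: int


def build_recurrence_plot(
    series,
    m: int = 3,
    delay: int = 1,
    radius_fraction: float = 0.2,
    theiler: int = 1,
) -> RecurrencePlot:
    """Threshold the embedded pairwise-distance matrix at a distance fraction."""
    x = np.asarray(series, dtype=float)
    n = x.size - (m - 1) * delay
    if n <= 10:
        raise ValueError("series too short for this embedding")
    X = np.column_stack([x[i * delay:i * delay + n] for i in range(m)])
    dist = squareform(pdist(X))
    dmax = dist.max()
    if dmax == 0:
        raise DegeneratePhaseSpaceError("constant series has a degenerate phase space")
    radius = radius_fraction * dmax
    matrix = dist <= radius
    return RecurrencePlot(matrix=matrix, m=m, delay=delay, radius=radius, theiler=theiler)


def _line_lengths(runs_of: np.ndarray) -> list[int]:
    """Lengths of True-runs in a 1-D boolean array."""
    out = []
    count = 0
    for v in runs_of:
        if v:
            count += 1
        elif count:
            out.append(count)
            count = 0
    if count:
        out.append(count)
    return out


def _entropy(lengths: list[int]) -> float:
    if not lengths:
        return np.nan
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def compute_rqa(plot: RecurrencePlot, l_min: int = 2, v_min: int = 2) -> dict[str, float]:
    """The 13 recurrence measures from one thresholded recurrence matrix."""
    R = plot.matrix
    n = R.shape[0]
    out = {c: np.nan for c in RQA_COLUMNS}

    # Theiler-masked copy used for recurrence-rate / diagonal / vertical counting
    masked = R.copy()
    for k in range(-plot.theiler, plot.theiler + 1):
        idx = np.arange(max(0, -k), min(n, n - k))
        masked[idx, idx + k] = False
    counted = n * n - sum(
        n - abs(k) for k in range(-plot.theiler, plot.theiler + 1)
    )
    n_rec = int(masked.sum())
    if counted <= 0:
        return out
    rr = n_rec / counted
    out["RecurrenceRate"] = rr

    # diagonal lines (both triangles; matrix symmetric)
    diag_lengths: list[int] = []
    for k in range(plot.theiler + 1, n):
        runs = _line_lengths(np.diagonal(masked, offset=k))
        diag_lengths.extend(runs + runs)  # lower triangle mirrors upper
    long_diags = [l for l in diag_lengths if l >= l_min]
    if n_rec > 0:
        out["Determinism"] = sum(long_diags) / n_rec
        if rr > 0:
            out["DeteRecRatio"] = out["Determinism"] / rr
    if long_diags:
        out["L"] = float(np.mean(long_diags))
        out["Divergence"] = 1.0 / max(long_diags)
        out["LEn"] = _entropy(long_diags)

    # vertical lines on the Theiler-masked matrix
    vert_lengths: list[int] = []
    for j in range(n):
        vert_lengths.extend(_line_lengths(masked[:, j]))
    long_verts = [l for l in vert_lengths if l >= v_min]
    if n_rec > 0:
        out["Laminarity"] = sum(long_verts) / n_rec
    if long_verts:
        out["TrappingTime"] = float(np.mean(long_verts))
        out["VMax"] = float(max(long_verts))
        out["VEn"] = _entropy(long_verts)

    # white vertical lines: gaps between recurrences in each column
    white = R.copy()
    np.fill_diagonal(white, True)
    white_lengths: list[int] = []
    for j in range(n):
        white_lengths.extend(_line_lengths(~white[:, j]))
    if white_lengths:
        out["W"] = float(np.mean(white_lengths))
        out["WMax"] = float(max(white_lengths))
        out["WEn"] = _entropy(white_lengths)
    return out
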