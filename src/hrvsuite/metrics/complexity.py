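"""Entropy, fractal, DFA/MFDFA and information-theoretic HRV metrics.

All estimators here are deterministic given the input series and the
parameter set. Tolerance-based entropies scale ``r`` by the series SD, so
they are invariant to adding a constant to the series; DFA integrates the
mean-removed series, giving the same invariance.

Interpretation choices that the source material leaves open are documented
on the individual functions (Petrosian variant, LZ symbolization, Fisher
information construction, multiscale summary scalar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

__all__ = [
    "ComplexityParams",
    "estimate_optimal_delay",
    "average_mutual_information",
    "approximate_entropy",
    "corrected_approximate_entropy",
    "sample_entropy",
    "fuzzy_entropy",
    "shannon_entropy",
    "spectral_entropy",
    "svd_entropy",
    "permutation_entropy",
    "weighted_permutation_entropy",
    "multiscale_permutation_entropy",
    "cumulative_residual_entropy",
    "differential_entropy",
    "fisher_information",
    "multiscale_entropy",
    "higuchi_fd",
    "katz_fd",
    "petrosian_fd",
    "sevcik_fd",
    "nld_fd",
    "sda_fd",
    "psd_slope",
    "relative_roughness",
    "hurst_exponent",
    "correlation_dimension",
    "lz76_complexity",
    "lempel_ziv_complexity",
    "permutation_lempel_ziv_complexity",
    "hjorth_complexity",
    "dfa",
    "mfdfa_features",
    "compute_entropy_family",
    "compute_fractal_family",
    "compute_dfa",
    "compute_mfdfa_features",
]


@dataclass(frozen=True)
class ComplexityParams:
    """Shared parameters for the complexity metric family."""

    m: int = 2
    r: float = 0.2  # tolerance as a fraction of the series SD
    delay: int = 1
    delay_max: int = 100
    scales: tuple = tuple(range(1, 11))
    q_list: tuple = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)
    alpha1_range: tuple = (4, 16)
    alpha2_range: tuple = (16, 64)
    kmax: int = 10

    def __post_init__(self):
        if self.m < 1 or self.r <= 0 or not 1 <= self.delay <= self.delay_max:
            raise ValueError("invalid complexity parameters")


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    """Delay-embedding matrix with rows as m-dimensional template vectors."""
    n = x.size - (m - 1) * delay
    if n <= 0:
        raise ValueError("series too short for this embedding")
    return np.column_stack([x[i * delay:i * delay + n] for i in range(m)])


# ---------------------------------------------------------------------------
# optimal embedding delay (first local minimum of average mutual information)

def average_mutual_information(x: np.ndarray, lag: int, bins: int | None = None) -> float:
    """Histogram estimate of the mutual information between x[t] and x[t+lag]."""
    a, b = x[:-lag], x[lag:]
    if bins is None:
        bins = max(4, int(np.sqrt(a.size / 5)))
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def estimate_optimal_delay(series: np.ndarray, delay_max: int = 100) -> int | None:
    """First local minimum of AMI over lags 1..delay_max (Fraser-Swinney).

    The histogram AMI estimate jitters, so the local minimum must be a
    *significant* dip: the value is within the estimator noise level of the
    running minimum and the curve rises by more than that level within the
    next few lags. Two guards keep the criterion well-behaved:

    * when the whole AMI curve stays below the independence bias level of
      the histogram estimator, the series carries no detectable lag
      dependence and the delay is 1 (i.i.d. data);
    * when no significant dip exists, the global AMI minimum is returned.

    Returns None when the series is too short for any lag.
    """
    x = np.asarray(series, dtype=float)
    max_lag = min(int(delay_max), x.size - 2)
    if max_lag < 1 or np.ptp(x) == 0:
        return None
    bins = max(4, int(np.sqrt(x.size / 5)))
    ami = np.array(
        [average_mutual_information(x, k, bins) for k in range(1, max_lag + 1)]
    )
    # chi-square independence scale of the histogram MI estimator
    n_eff = x.size - 1
    bias = (bins - 1) ** 2 / (2 * n_eff)
    noise = (bins - 1) / (np.sqrt(2) * n_eff)
    if ami.max() < bias + 6 * noise:
        return 1
    eps = min(4 * noise, 0.1 * np.ptp(ami))
    run_min = np.inf
    for k in range(ami.size - 1):
        run_min = min(run_min, ami[k])
        ahead = ami[k + 1:k + 4]
        if ami[k] <= run_min + eps and ahead.size and ahead.max() > ami[k] + eps:
            return k + 1
    return int(np.argmin(ami)) + 1


# ---------------------------------------------------------------------------
# regularity entropies

def _chebyshev_counts(x, m, r_abs, delay):
    """Pair-count matrices for template lengths m and m+1 (Chebyshev metric)."""
    Xm = _embed(x, m, delay)
    Xm1 = _embed(x, m + 1, delay)
    n1 = Xm1.shape[0]
    Dm = squareform(pdist(Xm[:n1], metric="chebyshev")) <= r_abs
    Dm1 = squareform(pdist(Xm1, metric="chebyshev")) <= r_abs
    return Dm, Dm1


def approximate_entropy(series, m=2, r=0.2, delay=1) -> float:
    """Classical ApEn with self-matches included, tolerance r * SD."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    r_abs = r * sd

    def phi(mm):
        X = _embed(x, mm, delay)
        D = squareform(pdist(X, metric="chebyshev")) <= r_abs
        # diagonal distances are 0 <= r, so self-matches are already counted
        c = D.sum(axis=1) / X.shape[0]
        return np.mean(np.log(c))

    return float(phi(m) - phi(m + 1))


def corrected_approximate_entropy(series, m=2, r=0.2, delay=1) -> float:
    """Corrected ApEn: self-matches excluded, zero-count templates skipped.

    The correction removes the self-match bias of classical ApEn; templates
    with no m- or (m+1)-matches are dropped from the average rather than
    forcing log(0).
    """
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    r_abs = r * sd
    Dm, Dm1 = _chebyshev_counts(x, m, r_abs, delay)
    np.fill_diagonal(Dm, False)
    np.fill_diagonal(Dm1, False)
    bm = Dm.sum(axis=1).astype(float)
    am = Dm1.sum(axis=1).astype(float)
    valid = (bm > 0) & (am > 0)
    if not np.any(valid):
        return np.nan
    return float(-np.mean(np.log(am[valid] / bm[valid])))


def sample_entropy(series, m=2, r=0.2, delay=1) -> float:
    """SampEn = -ln(A/B) over all template pairs, self-matches excluded."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    r_abs = r * sd
    a, b = _sampen_counts(x, m, r_abs, delay)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def _sampen_counts(x, m, r_abs, delay=1):
    Dm, Dm1 = _chebyshev_counts(x, m, r_abs, delay)
    n1 = Dm1.shape[0]
    iu = np.triu_indices(n1, k=1)
    b = int(Dm[iu].sum())
    a = int(Dm1[iu].sum())
    return a, b


def fuzzy_entropy(series, m=2, r=0.2, delay=1, order=2) -> float:
    """FuzzEn with exponential membership exp(-(d/r)^order), baseline removed."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    r_abs = r * sd

    def phi(mm):
        X = _embed(x, mm, delay)
        X = X - X.mean(axis=1, keepdims=True)
        d = pdist(X, metric="chebyshev")
        return np.mean(np.exp(-((d / r_abs) ** order)))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return np.nan
    return float(np.log(p_m) - np.log(p_m1))


def _fuzzy_sums(x, m, r_abs, delay=1, order=2):
    """Summed fuzzy memberships for lengths m and m+1 (for pooled multiscale)."""

    def total(mm):
        X = _embed(x, mm, delay)
        X = X - X.mean(axis=1, keepdims=True)
        d = pdist(X, metric="chebyshev")
        return float(np.sum(np.exp(-((d / r_abs) ** order)))), d.size

    a, na = total(m + 1)
    b, nb = total(m)
    return a, b, na, nb


def shannon_entropy(series, bins: int | None = None) -> float:
    """Shannon entropy (bits) of the histogram-symbolized series."""
    x = np.asarray(series, dtype=float)
    if bins is None:
        bins = max(1, int(np.ceil(np.sqrt(x.size))))
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def spectral_entropy(series, sampling_rate: float = 1.0) -> float:
    """Shannon entropy of the normalized PSD, normalized to [0, 1]."""
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        return np.nan
    freqs, power = sps.periodogram(x - x.mean(), fs=sampling_rate)
    power = power[1:]  # drop DC
    total = power.sum()
    if total <= 0 or power.size < 2:
        return np.nan
    p = power / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(power.size))


def svd_entropy(series, m=2, delay=1) -> float:
    """Shannon entropy (bits) of the normalized singular-value distribution."""
    x = np.asarray(series, dtype=float)
    X = _embed(x, m, delay)
    s = np.linalg.svd(X, compute_uv=False)
    total = s.sum()
    if total == 0:
        return np.nan
    p = s / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _ordinal_patterns(x, m=3, delay=1):
    X = _embed(x, m, delay)
    patterns = np.argsort(X, axis=1, kind="stable")
    # encode each permutation as a single integer
    codes = np.zeros(X.shape[0], dtype=np.int64)
    for i in range(m):
        codes = codes * m + patterns[:, i]
    return X, codes


def permutation_entropy(series, m=3, delay=1, normalize=True) -> float:
    """Ordinal-pattern entropy; normalized by log2(m!) when requested."""
    x = np.asarray(series, dtype=float)
    _, codes = _ordinal_patterns(x, m, delay)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log2(p))
    if normalize:
        h /= np.log2(float(math.factorial(m)))
    return float(h)


def weighted_permutation_entropy(series, m=3, delay=1, normalize=True) -> float:
    """PEn with each pattern weighted by its embedding-vector variance.

    Equals plain PEn when all weights are equal; falls back to PEn when the
    total weight is zero (constant series).
    """
    x = np.asarray(series, dtype=float)
    X, codes = _ordinal_patterns(x, m, delay)
    w = X.var(axis=1)
    total = w.sum()
    if total == 0:
        return permutation_entropy(series, m, delay, normalize)
    uniq = np.unique(codes)
    pw = np.array([w[codes == c].sum() for c in uniq]) / total
    pw = pw[pw > 0]
    h = -np.sum(pw * np.log2(pw))
    if normalize:
        h /= np.log2(float(math.factorial(m)))
    return float(h)


def _coarse_grain(x, scale):
    n = (x.size // scale) * scale
    return x[:n].reshape(-1, scale).mean(axis=1)


def multiscale_permutation_entropy(series, m=3, delay=1, scales=(1, 2, 3)) -> float:
    """Mean ordinal-pattern entropy over coarse-grained scales."""
    x = np.asarray(series, dtype=float)
    vals = []
    for s in scales:
        cg = _coarse_grain(x, s)
        if cg.size < m * 5:
            continue
        vals.append(permutation_entropy(cg, m, delay))
    return float(np.mean(vals)) if vals else np.nan


def cumulative_residual_entropy(series) -> float:
    """-integral of S(x) ln S(x) dx on the empirical survival function."""
    x = np.sort(np.asarray(series, dtype=float))
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        return 0.0
    surv = 1.0 - np.arange(1, n) / n  # S on the gap (x[i-1], x[i])
    gaps = np.diff(x)
    mask = surv > 0
    return float(-np.sum(surv[mask] * np.log(surv[mask]) * gaps[mask]))


def differential_entropy(series, bins: int | None = None) -> float:
    """Histogram-density differential entropy (nats)."""
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        return np.nan
    if bins is None:
        bins = max(2, int(np.ceil(np.sqrt(x.size))))
    counts, edges = np.histogram(x, bins=bins)
    w = edges[1] - edges[0]
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)) + np.log(w))


def fisher_information(series, m=2, delay=1) -> float:
    """Fisher information of the normalized singular-value spectrum.

    Constructed as sum_i (p[i+1] - p[i])^2 / p[i] over the singular values
    of the delay-embedded matrix (documented interpretation).
    """
    x = np.asarray(series, dtype=float)
    X = _embed(x, m, delay)
    s = np.linalg.svd(X, compute_uv=False)
    total = s.sum()
    if total == 0:
        return np.nan
    p = s / total
    p = p[p > 0]
    if p.size < 2:
        return 0.0
    return float(np.sum(np.diff(p) ** 2 / p[:-1]))


# ---------------------------------------------------------------------------
# multiscale entropies

def multiscale_entropy(
    series,
    variant: str = "MSE",
    m: int = 2,
    r: float = 0.2,
    scales=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    delay: int = 1,
    min_points: int = 10,
) -> tuple[float, dict[int, float]]:
    """Coarse-grained entropy curves summarized as the mean over valid scales.

    Variants: MSE (plain coarse-grain SampEn), CMSE (SampEn averaged over
    all composite offsets), RCMSE (match counts pooled across offsets before
    the log), FuzzEnMSE / FuzzEnRCMSE (fuzzy membership kernel). The
    tolerance is fixed from the SD of the *original* series. Scales with too
    little data are dropped. Returns ``(summary, per_scale_curve)``.
    """
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0, {int(s): 0.0 for s in scales}
    r_abs = r * sd
    fuzzy = variant.startswith("FuzzEn")
    base = variant[6:] if fuzzy else variant
    curve: dict[int, float] = {}
    for s in scales:
        s = int(s)
        if x.size // s < max(min_points, (m + 1) * delay + 1):
            continue
        offsets = range(s) if base in ("CMSE", "RCMSE") else range(1)
        vals, a_tot, b_tot = [], 0.0, 0.0
        for off in offsets:
            cg = x[off:][:(x.size - off) // s * s].reshape(-1, s).mean(axis=1)
            if cg.size < (m + 1) * delay + 1:
                continue
            if fuzzy:
                a, b, _, _ = _fuzzy_sums(cg, m, r_abs, delay)
            else:
                a, b = _sampen_counts(cg, m, r_abs, delay)
            a_tot += a
            b_tot += b
            if a > 0 and b > 0:
                vals.append(-np.log(a / b))
        if base == "RCMSE":
            if a_tot > 0 and b_tot > 0:
                curve[s] = float(-np.log(a_tot / b_tot))
        elif vals:
            curve[s] = float(np.mean(vals))
    summary = float(np.mean(list(curve.values()))) if curve else np.nan
    return summary, curve


# ---------------------------------------------------------------------------
# fractal dimensions and scaling exponents

def higuchi_fd(series, kmax=10) -> float:
    """Higuchi fractal dimension of the series viewed as a curve."""
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        return 1.0  # flat curve: dimension of a straight line
    n = x.size
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            L = np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / (((idx.size - 1) * k) * k)
            lengths.append(L)
        if lengths:
            lk.append(np.log(np.mean(lengths)))
            ks.append(np.log(1.0 / k))
    if len(lk) < 2:
        return np.nan
    slope = np.polyfit(ks, lk, 1)[0]
    return float(slope)


def katz_fd(series) -> float:
    """Katz fractal dimension of the planar waveform (unit x-spacing).

    D = log10(L/a) / log10(d/a) with L the curve length, a the mean step and
    d the maximum distance from the first point, all measured on the planar
    curve (i, y_i). Exactly 1.0 for a straight line.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        return np.nan
    steps = np.hypot(1.0, np.diff(y))
    L = steps.sum()
    a = steps.mean()
    x = np.arange(y.size, dtype=float)
    d = np.max(np.hypot(x - x[0], y - y[0]))
    if d <= 0 or a <= 0 or d == a:
        return np.nan
    return float(np.log10(L / a) / np.log10(d / a))


def petrosian_fd(series) -> float:
    """Petrosian FD; the binary sequence marks sign changes of the first
    difference (variant choice documented in the output metadata)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    d = np.diff(x)
    signs = np.sign(d)
    nz = signs[signs != 0]
    n_delta = int(np.sum(np.diff(nz) != 0)) if nz.size > 1 else 0
    if n < 2:
        return np.nan
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta))))


def sevcik_fd(series) -> float:
    """Sevcik FD on the unit-square normalized waveform."""
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 3 or np.ptp(y) == 0:
        return 1.0
    ys = (y - y.min()) / np.ptp(y)
    xs = np.linspace(0.0, 1.0, n)
    L = float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))
    return float(1.0 + (np.log(L) - np.log(2.0)) / np.log(2.0 * (n - 1)))


def nld_fd(series, a=1.9079, k=0.3523, b=0.3527) -> float:
    """Normalized length density FD for short epochs.

    The series is amplitude-normalized to [0, 1]; NLD is the mean absolute
    increment and is mapped to an FD through a documented power-law
    calibration ``FD = a * NLD**k + b``.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        return np.nan
    rng = np.ptp(y)
    if rng == 0:
        return 1.0
    ys = (y - y.min()) / rng
    nld = float(np.mean(np.abs(np.diff(ys))))
    if nld == 0:
        return 1.0
    return float(a * nld ** k + b)


def sda_fd(series, min_bin=4) -> float:
    """Standardized dispersion analysis: FD = 1 - slope of log SD-of-bin-means
    versus log bin size on the z-scored series. White noise gives FD = 1.5."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0 or x.size < min_bin * 8:
        return np.nan
    z = (x - x.mean()) / sd
    sizes, disps = [], []
    b = min_bin
    while x.size // b >= 4:
        means = _coarse_grain(z, b)
        disps.append(np.std(means, ddof=1))
        sizes.append(b)
        b *= 2
    if len(sizes) < 2:
        return np.nan
    slope = np.polyfit(np.log(sizes), np.log(disps), 1)[0]
    return float(1.0 - slope)


def psd_slope(series, sampling_rate: float = 1.0) -> float:
    """Slope of the log-log periodogram (0 for white noise, -2 for Brownian)."""
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        return np.nan
    freqs, power = sps.periodogram(x - x.mean(), fs=sampling_rate)
    mask = (freqs > 0) & (power > 0)
    if mask.sum() < 8:
        return np.nan
    return float(np.polyfit(np.log10(freqs[mask]), np.log10(power[mask]), 1)[0])


def relative_roughness(series) -> float:
    """Ratio of the lag-1 autocovariance to the lag-0 autocovariance."""
    x = np.asarray(series, dtype=float)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0 or x.size < 2:
        return np.nan
    return float(np.dot(xc[:-1], xc[1:]) / denom)


def _expected_rs(n: int) -> float:
    """Anis-Lloyd-Peters expected R/S of an i.i.d. series of length n."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        front = np.exp(gammaln((n - 1) / 2) - gammaln(n / 2)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2)
    return float((n - 0.5) / n * front * s)


def hurst_exponent(series, min_window=16) -> float:
    """Rescaled-range Hurst exponent with Anis-Lloyd small-sample correction."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < min_window * 4 or np.ptp(x) == 0:
        return np.nan
    sizes = []
    w = min_window
    while w <= n // 2:
        sizes.append(w)
        w *= 2
    log_rs, log_exp, log_n = [], [], []
    for w in sizes:
        k = n // w
        rs_vals = []
        for j in range(k):
            seg = x[j * w:(j + 1) * w]
            dev = np.cumsum(seg - seg.mean())
            r = np.ptp(dev)
            s = seg.std(ddof=1)
            if s > 0:
                rs_vals.append(r / s)
        if rs_vals:
            log_rs.append(np.log(np.mean(rs_vals)))
            log_exp.append(np.log(_expected_rs(w)))
            log_n.append(np.log(w))
    if len(log_n) < 2:
        return np.nan
    slope_actual = np.polyfit(log_n, log_rs, 1)[0]
    slope_expected = np.polyfit(log_n, log_exp, 1)[0]
    return float(0.5 + slope_actual - slope_expected)


def correlation_dimension(series, m=2, delay=1, n_radii=12) -> float:
    """Grassberger-Procaccia correlation dimension at embedding m."""
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        return np.nan
    X = _embed(x, m, delay)
    d = pdist(X)
    d = d[d > 0]
    if d.size < 100:
        return np.nan
    r_lo, r_hi = np.percentile(d, [10, 70])
    if r_lo <= 0 or r_hi <= r_lo:
        return np.nan
    radii = np.geomspace(r_lo, r_hi, n_radii)
    c = np.array([np.mean(d < r) for r in radii])
    mask = c > 0
    if mask.sum() < 3:
        return np.nan
    return float(np.polyfit(np.log(radii[mask]), np.log(c[mask]), 1)[0])


def lz76_complexity(symbols) -> int:
    """LZ76 phrase count (Kaspar-Schuster scan) of a symbol sequence."""
    s = list(symbols)
    n = len(s)
    if n == 0:
        return 0
    c, i, k, l = 1, 0, 1, 1
    k_max = 1
    while True:
        if l + k > n:
            c += 1
            break
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lempel_ziv_complexity(series) -> float:
    """Median-binarized, LZ76-parsed, normalized Lempel-Ziv complexity."""
    x = np.asarray(series, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0
    symbols = (x >= np.median(x)).astype(int)
    c = lz76_complexity(symbols)
    n = x.size
    return float(c * np.log2(n) / n)


def permutation_lempel_ziv_complexity(series, m=3, delay=1) -> float:
    """LZ76 complexity of the ordinal-pattern symbol stream, normalized."""
    x = np.asarray(series, dtype=float)
    if x.size < m * delay + 2:
        return np.nan
    _, codes = _ordinal_patterns(x, m, delay)
    c = lz76_complexity(codes.tolist())
    n = codes.size
    alphabet = float(math.factorial(m))
    return float(c * np.log(n) / (np.log(alphabet) * n))


def hjorth_complexity(series) -> float:
    """Hjorth complexity: mobility of the derivative over signal mobility."""
    x = np.asarray(series, dtype=float)
    dx = np.diff(x)
    ddx = np.diff(dx)
    vx, vdx, vddx = x.var(), dx.var(), ddx.var()
    if vx == 0 or vdx == 0:
        return np.nan
    mob = np.sqrt(vdx / vx)
    mob_d = np.sqrt(vddx / vdx)
    return float(mob_d / mob)


# ---------------------------------------------------------------------------
# detrended fluctuation analysis

def _dfa_fluctuations(x: np.ndarray, scales: np.ndarray, order: int = 1):
    """Window-wise squared fluctuations of the integrated series per scale.

    Windows are taken from both ends of the profile so trailing data is not
    discarded. Returns ``{scale: array of per-window mean squared residuals}``.
    """
    profile = np.cumsum(x - x.mean())
    n = profile.size
    out = {}
    for s in scales:
        s = int(s)
        k = n // s
        if k < 2:
            continue
        segs = []
        for sl in (profile[:k * s], profile[-k * s:]):
            segs.append(sl.reshape(k, s))
        windows = np.vstack(segs)
        t = np.arange(s)
        # order-1 detrend per window via least squares
        coeffs = np.polyfit(t, windows.T, order)
        trend = np.polyval(coeffs, t[:, None]).T
        out[s] = np.mean((windows - trend) ** 2, axis=1)
    return out


def dfa(series, scale_range=(4, 64), order: int = 1) -> float:
    """Monofractal DFA exponent over the given beat-scale range."""
    x = np.asarray(series, dtype=float)
    lo, hi = scale_range
    if x.size < 4 * lo or np.ptp(x) == 0:
        return np.nan
    scales = np.unique(np.geomspace(lo, min(hi, x.size // 4), 10).astype(int))
    fluct = _dfa_fluctuations(x, scales, order)
    log_n, log_f = [], []
    for s, f2 in fluct.items():
        val = np.sqrt(np.mean(f2))
        if val > 0:
            log_n.append(np.log(s))
            log_f.append(np.log(val))
    if len(log_n) < 3:
        return np.nan
    return float(np.polyfit(log_n, log_f, 1)[0])


def mfdfa_features(series, q_list=(-5, -4, -3, -2, -1, 1, 2, 3, 4, 5),
                   scale_range=(4, 16), order: int = 1) -> dict[str, float]:
    """Singularity-spectrum summaries from multifractal DFA.

    q-order fluctuation functions give generalized Hurst exponents h(q);
    the Legendre transform of tau(q) = q h(q) - 1 yields the spectrum
    (alpha, f(alpha)). Summary definitions: Width = alpha range; Peak =
    alpha at the spectrum maximum; Mean = mean alpha; Max = max f;
    Delta = h(q_min) - h(q_max); Asymmetry = left minus right width about
    the peak; Fluctuation = mean fluctuation amplitude over scales and q;
    Increment = mean |successive difference of h(q)| (both documented
    interpretations).
    """
    keys = ["Width", "Peak", "Mean", "Max", "Delta", "Asymmetry",
            "Fluctuation", "Increment"]
    out = {k: np.nan for k in keys}
    x = np.asarray(series, dtype=float)
    lo, hi = scale_range
    if x.size < 4 * lo or np.ptp(x) == 0:
        return out
    q = np.asarray([qq for qq in q_list if qq != 0], dtype=float)
    scales = np.unique(np.geomspace(lo, min(hi, x.size // 4), 8).astype(int))
    fluct = _dfa_fluctuations(x, scales, order)
    if len(fluct) < 3:
        return out
    used_scales = sorted(fluct)
    Fq = np.full((q.size, len(used_scales)), np.nan)
    for j, s in enumerate(used_scales):
        f2 = np.maximum(fluct[s], 1e-300)
        for i, qq in enumerate(q):
            Fq[i, j] = np.mean(f2 ** (qq / 2.0)) ** (1.0 / qq)
    log_s = np.log(used_scales)
    h = np.array([np.polyfit(log_s, np.log(Fq[i]), 1)[0] for i in range(q.size)])
    tau = q * h - 1.0
    if q.size < 2:  # single-q call: spectrum degenerates to the DFA exponent
        alpha = h.copy()
        f_alpha = np.ones_like(h)
    else:
        alpha = np.gradient(tau, q)
        f_alpha = q * alpha - tau
    out["Width"] = float(alpha.max() - alpha.min())
    peak_idx = int(np.argmax(f_alpha))
    out["Peak"] = float(alpha[peak_idx])
    out["Mean"] = float(alpha.mean())
    out["Max"] = float(f_alpha.max())
    out["Delta"] = float(h[0] - h[-1])  # q ascending: h(q_min) - h(q_max)
    out["Asymmetry"] = float(
        (alpha[peak_idx] - alpha.min()) - (alpha.max() - alpha[peak_idx])
    )
    out["Fluctuation"] = float(np.mean(Fq))
    out["Increment"] = float(np.mean(np.abs(np.diff(h)))) if h.size > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# family-level entry points used by the segment pipeline

def compute_entropy_family(series, params: ComplexityParams,
                           optimal_delay: int | None = None) -> dict[str, float]:
    """Entropy/information metrics for one segment.

    The fuzzy/cApEn pathway uses the segment-specific optimal delay when one
    is supplied; the classical ApEn/SampEn columns use the configured
    (default 1) delay.
    """
    x = np.asarray(series, dtype=float)
    d_opt = optimal_delay if optimal_delay is not None else params.delay
    out: dict[str, float] = {}
    out["ApEn"] = approximate_entropy(x, params.m, params.r, params.delay)
    out["SampEn"] = sample_entropy(x, params.m, params.r, params.delay)
    out["cApEn"] = corrected_approximate_entropy(x, params.m, params.r, d_opt)
    out["FuzzEn"] = fuzzy_entropy(x, params.m, params.r, d_opt)
    out["ShanEn"] = shannon_entropy(x)
    out["SpEn"] = spectral_entropy(x)
    out["SVDEn"] = svd_entropy(x, params.m, params.delay)
    out["PEn"] = permutation_entropy(x)
    out["WPEn"] = weighted_permutation_entropy(x)
    out["MSPEn"] = multiscale_permutation_entropy(x)
    out["CREn"] = cumulative_residual_entropy(x)
    out["DiffEn"] = differential_entropy(x)
    out["FI"] = fisher_information(x, params.m, params.delay)
    return out


def compute_fractal_family(series, params: ComplexityParams) -> dict[str, float]:
    """Fractal-dimension / scaling / symbolic-complexity metrics."""
    x = np.asarray(series, dtype=float)
    return {
        "HFD": higuchi_fd(x, params.kmax),
        "KFD": katz_fd(x),
        "PFD": petrosian_fd(x),
        "SFD": sevcik_fd(x),
        "NLD": nld_fd(x),
        "SDA": sda_fd(x),
        "PSDslope": psd_slope(x),
        "RR": relative_roughness(x),
        "Hurst": hurst_exponent(x),
        "CorrDim": correlation_dimension(x, params.m, params.delay),
        "LZC": lempel_ziv_complexity(x),
        "PLZC": permutation_lempel_ziv_complexity(x),
        "Hjorth": hjorth_complexity(x),
    }


def compute_dfa(series, params: ComplexityParams) -> dict[str, float]:
    """DFA exponents: overall, short-range (alpha1) and long-range (alpha2)."""
    x = np.asarray(series, dtype=float)
    return {
        "DFA": dfa(x, (params.alpha1_range[0], params.alpha2_range[1])),
        "DFA_alpha1": dfa(x, params.alpha1_range),
        "DFA_alpha2": dfa(x, params.alpha2_range),
    }


def compute_mfdfa_features(series, params: ComplexityParams) -> dict[str, float]:
    """MFDFA singularity-spectrum summaries for both scale ranges."""
    x = np.asarray(series, dtype=float)
    out = {}
    for label, rng in (("alpha1", params.alpha1_range), ("alpha2", params.alpha2_range)):
        feats = mfdfa_features(x, params.q_list, rng)
        for k, v in feats.items():
            out[f"MFDFA_{label}_{k}"] = v
    return out
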