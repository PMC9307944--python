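import numpy as np
import pytest

from hrvsuite.metrics import complexity as cx


# ---------------------------------------------------------------------------
# independent oracles

def brute_sampen(x, m, r_abs, delay=1):
    """O(n^2) template counting straight from the definition."""
    def templates(mm):
        n = len(x) - (mm - 1) * delay
        return [x[i:i + (mm - 1) * delay + 1:delay] for i in range(n)]

    def count(mm):
        t = templates(mm)
        c = 0
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                if max(abs(a - b) for a, b in zip(t[i], t[j])) <= r_abs:
                    c += 1
        return c

    n1 = len(x) - m * delay
    t_m = templates(m)[:n1]
    b = 0
    for i in range(len(t_m)):
        for j in range(i + 1, len(t_m)):
            if max(abs(a - b_) for a, b_ in zip(t_m[i], t_m[j])) <= r_abs:
                b += 1
    a = count(m + 1)
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


def brute_apen(x, m, r_abs, delay=1):
    """Definition-level ApEn with self-matches."""
    def phi(mm):
        n = len(x) - (mm - 1) * delay
        t = [x[i:i + (mm - 1) * delay + 1:delay] for i in range(n)]
        logs = []
        for i in range(n):
            c = sum(
                1
                for j in range(n)
                if max(abs(a - b) for a, b in zip(t[i], t[j])) <= r_abs
            )
            logs.append(np.log(c / n))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


def brute_lz76(symbols):
    """Independent LZ76 parse: longest reproducible prefix plus one symbol."""
    s = "".join(str(v) for v in symbols)
    n = len(s)
    phrases = 0
    pos = 0
    while pos < n:
        length = 1
        # grow while s[pos:pos+length] occurs starting before pos
        while pos + length <= n and s[pos:pos + length] in s[:pos + length - 1]:
            length += 1
        phrases += 1
        pos += length
    return phrases


# ---------------------------------------------------------------------------
# oracle equivalence

@pytest.mark.parametrize("delay", [1, 2])
@pytest.mark.parametrize("n", [60, 200])
def test_sampen_matches_brute_force(rng, n, delay):
    x = rng.normal(0, 1, n)
    r_abs = 0.2 * x.std()
    expected = brute_sampen(list(x), 2, r_abs, delay)
    got = cx.sample_entropy(x, m=2, r=0.2, delay=delay)
    assert got == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("n", [60, 150])
def test_apen_matches_brute_force(rng, n):
    x = rng.normal(0, 1, n)
    r_abs = 0.2 * x.std()
    expected = brute_apen(list(x), 2, r_abs)
    got = cx.approximate_entropy(x, m=2, r=0.2)
    assert got == pytest.approx(expected, rel=1e-12)


def test_lz76_all_identical_is_two():
    assert cx.lz76_complexity([1] * 10) == 2
    assert brute_lz76([1] * 10) == 2


@pytest.mark.parametrize("seed", range(5))
def test_lz76_matches_independent_parser(seed):
    rng = np.random.default_rng(seed)
    symbols = rng.integers(0, 2, 80).tolist()
    assert cx.lz76_complexity(symbols) == brute_lz76(symbols)


# ---------------------------------------------------------------------------
# entropy family

def test_constant_series_entropies():
    x = np.full(200, 800.0)
    assert cx.sample_entropy(x) == 0.0
    assert cx.permutation_entropy(x) == 0.0
    assert cx.shannon_entropy(x) == 0.0


def test_monotone_single_ordinal_pattern():
    assert cx.permutation_entropy(np.arange(100.0), m=3) == 0.0


def test_sampen_orders_noise_above_sine(rng):
    noise = rng.normal(0, 1, 1000)
    sine = np.sin(2 * np.pi * np.arange(1000) / 50)
    assert cx.sample_entropy(noise, 2, 0.2) > cx.sample_entropy(sine, 2, 0.2)


def test_shift_invariance(rng):
    x = rng.normal(800, 50, 300)
    for fn in (cx.sample_entropy, cx.approximate_entropy, cx.fuzzy_entropy):
        assert fn(x) == pytest.approx(fn(x + 500.0), rel=1e-9)
    assert cx.dfa(x, (4, 16)) == pytest.approx(cx.dfa(x + 500.0, (4, 16)), rel=1e-9)


def test_wpen_equals_pen_for_equal_weights():
    # alternating two values: every embedding vector has the same variance
    x = np.asarray([1.0, 2.0] * 50)
    assert cx.weighted_permutation_entropy(x, m=3) == pytest.approx(
        cx.permutation_entropy(x, m=3), rel=1e-12
    )


def test_pen_normalized_range(rng):
    assert 0 <= cx.permutation_entropy(rng.normal(size=500)) <= 1


def test_spectral_entropy_sine_below_noise(rng):
    sine = np.sin(2 * np.pi * np.arange(2048) / 64)
    noise = rng.normal(size=2048)
    assert cx.spectral_entropy(sine) < cx.spectral_entropy(noise)
    assert 0 <= cx.spectral_entropy(noise) <= 1


def test_cren_shift_invariant_nonnegative(rng):
    x = rng.normal(800, 50, 500)
    assert cx.cumulative_residual_entropy(x) >= 0
    assert cx.cumulative_residual_entropy(x) == pytest.approx(
        cx.cumulative_residual_entropy(x + 100), rel=1e-9
    )


# ---------------------------------------------------------------------------
# optimal delay

def test_delay_sine_quarter_period():
    t = np.arange(800)
    x = np.sin(2 * np.pi * t / 40)
    delay = cx.estimate_optimal_delay(x, delay_max=30)
    assert abs(delay - 10) <= 2


def test_delay_white_noise_is_one():
    rng = np.random.default_rng(42)
    x = rng.normal(size=2000)
    assert cx.estimate_optimal_delay(x, delay_max=20) == 1


def test_delay_respects_bound(rng):
    x = rng.normal(size=500)
    assert cx.estimate_optimal_delay(x, delay_max=5) <= 5


def test_delay_too_short_returns_none():
    assert cx.estimate_optimal_delay(np.asarray([1.0, 2.0]), delay_max=10) is None


# ---------------------------------------------------------------------------
# multiscale entropy

def test_mse_scale_one_is_raw_sampen(rng):
    x = rng.normal(800, 50, 400)
    summary, curve = cx.multiscale_entropy(x, "MSE", scales=(1,))
    assert summary == pytest.approx(cx.sample_entropy(x), rel=1e-12)


def test_mse_white_noise_decreasing(rng):
    x = rng.normal(0, 1, 5000)
    _, curve = cx.multiscale_entropy(x, "MSE", scales=(1, 2, 4, 8))
    assert curve[1] > curve[8]


def test_rcmse_survives_where_mse_missing(rng):
    # short series at a large scale: single-offset counts can vanish while
    # pooled counts survive
    x = rng.normal(0, 1, 130)
    _, mse_curve = cx.multiscale_entropy(x, "MSE", scales=(6,), min_points=10)
    _, rcmse_curve = cx.multiscale_entropy(x, "RCMSE", scales=(6,), min_points=10)
    assert 6 in rcmse_curve
    if 6 in mse_curve:
        assert np.isfinite(rcmse_curve[6])


def test_fuzzy_mse_defined(rng):
    x = rng.normal(800, 40, 400)
    summary, curve = cx.multiscale_entropy(x, "FuzzEnMSE", scales=(1, 2, 3))
    assert np.isfinite(summary) and len(curve) == 3


# ---------------------------------------------------------------------------
# fractal family

def test_katz_straight_line_exact():
    assert cx.katz_fd(np.linspace(0, 100, 1000)) == pytest.approx(1.0, abs=1e-9)


def test_petrosian_monotone_near_one():
    assert cx.petrosian_fd(np.arange(500.0)) == pytest.approx(1.0, abs=0.01)


def test_sda_white_noise(rng):
    vals = [cx.sda_fd(rng.normal(size=4096)) for _ in range(20)]
    assert np.mean(vals) == pytest.approx(1.5, abs=0.1)


def test_psd_slope_white_noise(rng):
    vals = [cx.psd_slope(rng.normal(size=4096)) for _ in range(20)]
    assert np.mean(vals) == pytest.approx(0.0, abs=0.15)


def test_psd_slope_brownian(rng):
    vals = [cx.psd_slope(np.cumsum(rng.normal(size=4096))) for _ in range(10)]
    assert np.mean(vals) == pytest.approx(-2.0, abs=0.3)


def test_relative_roughness_white_vs_smooth(rng):
    white = rng.normal(size=2000)
    assert abs(cx.relative_roughness(white)) < 0.1
    smooth = np.cumsum(rng.normal(size=2000))
    assert cx.relative_roughness(smooth) > 0.9


def test_hurst_white_noise(rng):
    assert cx.hurst_exponent(rng.normal(size=10_000)) == pytest.approx(0.5, abs=0.07)


def test_hjorth_complexity_positive(rng):
    assert cx.hjorth_complexity(rng.normal(size=500)) > 0


def test_higuchi_white_noise_near_two(rng):
    assert cx.higuchi_fd(rng.normal(size=2000)) == pytest.approx(2.0, abs=0.15)


def test_corrdim_sine_near_one():
    x = np.sin(2 * np.pi * np.arange(1000) / 40)
    d = cx.correlation_dimension(x, m=3, delay=10)
    assert 0.5 < d < 1.6


def test_lzc_regular_below_random(rng):
    regular = np.tile([1.0, 2.0], 500)
    random = rng.normal(size=1000)
    assert cx.lempel_ziv_complexity(regular) < cx.lempel_ziv_complexity(random)


# ---------------------------------------------------------------------------
# DFA / MFDFA

def test_dfa_white_noise(rng):
    # the 4-16 beat window carries a known small-scale bias; the asymptotic
    # white-noise limit is recovered on the 16-64 range
    assert cx.dfa(rng.normal(size=10_000), (16, 64)) == pytest.approx(0.5, abs=0.05)


def test_dfa_integrated_white_noise(rng):
    x = np.cumsum(rng.normal(size=10_000))
    assert cx.dfa(x, (4, 64)) == pytest.approx(1.5, abs=0.1)


def test_dfa_insufficient_scale_missing(rng):
    assert np.isnan(cx.dfa(rng.normal(size=50), (16, 64)))


def binomial_cascade(n_levels=12, p=0.7, seed=0):
    """Canonical multifractal measure via multiplicative splitting."""
    x = np.ones(1)
    rng = np.random.default_rng(seed)
    for _ in range(n_levels):
        left = np.where(rng.uniform(size=x.size) < 0.5, p, 1 - p)
        x = np.column_stack([x * left, x * (1 - left)]).ravel()
    return x


def test_mfdfa_white_noise_narrow(rng):
    feats = cx.mfdfa_features(rng.normal(size=4096), scale_range=(16, 256))
    assert feats["Width"] < 0.3


def test_mfdfa_cascade_wider_than_noise(rng):
    cascade = binomial_cascade(12)
    noise = rng.normal(size=cascade.size)
    w_c = cx.mfdfa_features(cascade, scale_range=(16, 256))["Width"]
    w_n = cx.mfdfa_features(noise, scale_range=(16, 256))["Width"]
    assert w_c > w_n


def test_mfdfa_q2_reduces_to_dfa(rng):
    x = rng.normal(size=4096)
    feats_range = (8, 64)
    h2 = None
    # with a single q the generalized exponent is exactly the q=2 DFA slope
    q = [2]
    # reuse the internal machinery through the public API
    feats = cx.mfdfa_features(x, q_list=q, scale_range=feats_range)
    # Delta = h(qmin) - h(qmax) = 0 for a single q; recompute h2 via DFA
    alpha = cx.dfa(x, feats_range)
    assert feats["Mean"] == pytest.approx(alpha, abs=0.05)


def test_params_validation():
    with pytest.raises(ValueError):
        cx.ComplexityParams(m=0)
    with pytest.raises(ValueError):
        cx.ComplexityParams(delay=5, delay_max=2)
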