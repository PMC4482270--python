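import numpy as np
import pytest
from scipy import stats

from eegbm import connectivity as conn
from tests.conftest import filtered_noise_epochs


def _unit(x):
    x = x - x.mean()
    return x / x.std()


def test_autocorrelation_peak_at_zero(rng):
    x = _unit(rng.standard_normal(400))
    res = conn.max_crosscorr(x, x, 200.0)
    assert res.r_max == pytest.approx(1.0, abs=1e-9)
    assert res.tau_max_ms == 0.0
    assert res.r_zero == pytest.approx(1.0, abs=1e-9)


def test_delayed_copy_recovers_lag(rng):
    fs = 200.0
    x = _unit(rng.standard_normal(400))
    y = np.roll(x, 10)  # y delayed by 10 samples = 50 ms: x leads
    res = conn.max_crosscorr(x, y, fs)
    assert abs(res.tau_max_ms) == pytest.approx(50.0)
    assert res.tau_max_ms == 50.0  # positive: second signal lags
    assert res.r_max > 0.9


def test_symmetry_under_swap(rng):
    fs = 200.0
    x = _unit(rng.standard_normal(400))
    y = _unit(np.roll(x, 7) + 0.5 * rng.standard_normal(400))
    a = conn.max_crosscorr(x, y, fs)
    b = conn.max_crosscorr(y, x, fs)
    assert a.r_max == pytest.approx(b.r_max, abs=1e-12)
    assert a.tau_max_ms == -b.tau_max_ms


def test_crosscorr_matches_brute_force(rng):
    fs = 64.0
    x = _unit(rng.standard_normal(64))
    y = _unit(rng.standard_normal(64))
    lags_ms, r = conn.crosscorr_lags(x, y, fs, max_lag_ms=250.0)
    n = 64
    for lag_ms, r_val in zip(lags_ms, r):
        tau = int(round(lag_ms / 1000.0 * fs))
        acc = sum(
            x[t] * y[t + tau] for t in range(n) if 0 <= t + tau < n
        )
        assert r_val == pytest.approx(acc / n, abs=1e-10)


def test_max_lag_must_fit_epoch(rng):
    with pytest.raises(ValueError, match="lag"):
        conn.max_crosscorr(rng.standard_normal(50), rng.standard_normal(50),
                           200.0, max_lag_ms=500.0)


def test_epoch_matrix_consistent_with_pairwise(rng):
    fs = 200.0
    epoch = rng.standard_normal((400, 5))
    epoch = (epoch - epoch.mean(0)) / epoch.std(0)
    pairs, lags_ms, r = conn.epoch_crosscorr_matrix(epoch, fs)
    k = pairs.index((1, 3))
    single = conn.max_crosscorr(epoch[:, 1], epoch[:, 3], fs)
    np.testing.assert_allclose(r[k], single.r, atol=1e-12)


def test_analytic_model_from_constant_curves_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        conn.fit_significance_model(np.ones((10, 201)))


def test_sigma2_is_variance_of_identical_curves(rng):
    curve = rng.standard_normal(201) * 0.05
    model = conn.fit_significance_model(np.tile(curve, (30, 1)))
    assert model.sigma2 == pytest.approx(curve.var(ddof=1))


def test_edge_pvalue_boundaries_and_monotonicity():
    model = conn.SignificanceModel(sigma2=0.0025, l_eff=100.0)
    assert conn.edge_pvalue(0.0, model) == pytest.approx(1.0)
    grid = np.linspace(0.0, 0.9, 50)
    p = conn.edge_pvalue(grid, model)
    assert np.all(np.diff(p) <= 0)
    assert np.all((p > 0) & (p <= 1))


def test_empirical_edge_pvalue_monotone(rng):
    sc = conn.subject_connectivity(filtered_noise_epochs(rng, 12), 200.0)
    assert sc.model.empirical
    grid = np.linspace(0.0, 12.0, 60)
    p = conn.edge_pvalue(grid, sc.model)
    assert np.all(np.diff(p) <= 1e-12)
    assert conn.edge_pvalue(0.0, sc.model) == pytest.approx(1.0)


def test_zero_lag_pvalue_uncorrected_analytic():
    model = conn.SignificanceModel(sigma2=0.01, l_eff=100.0)
    r = 0.2
    expected = 2 * stats.norm.sf(np.arctanh(r), scale=0.1)
    assert conn.zero_lag_pvalue(r, model) == pytest.approx(expected)
    # the edge test corrects for the lag search, the zero-lag test does not
    assert conn.edge_pvalue(r, model) > conn.zero_lag_pvalue(r, model)


def test_circular_shift_surrogate_flags_real_coupling(rng):
    fs = 200.0
    src = _unit(rng.standard_normal(400))
    x = _unit(src + 0.3 * rng.standard_normal(400))
    y = _unit(np.roll(src, 8) + 0.3 * rng.standard_normal(400))
    p_coupled = conn.circular_shift_pvalue(x, y, fs, n_surrogates=99, seed=0)
    # on a 2 s epoch a circular shift can land the coupling peak back inside
    # the +/-500 ms window, so the surrogate p is conservative but still small
    assert p_coupled <= 0.05
    a = _unit(rng.standard_normal(400))
    b = _unit(rng.standard_normal(400))
    p_null = conn.circular_shift_pvalue(a, b, fs, n_surrogates=99, seed=0)
    assert p_null > 0.05
    assert p_coupled < p_null


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

def test_coherence_transform_hand_value():
    assert conn.coherence_f_statistic(0.5, nu0=10) == pytest.approx(9.0)
    assert conn.coherence_f_statistic(0.0, nu0=10) == 0.0
    assert np.isinf(conn.coherence_f_statistic(1.0, nu0=10))


def test_coherence_statistic_strictly_increasing():
    msc = np.linspace(0.0, 0.99, 100)
    f = conn.coherence_f_statistic(msc, nu0=16)
    assert np.all(np.diff(f) > 0)


def test_coherence_config_degrees_of_freedom():
    assert conn.COHERENCE_5HZ.nu0 == 16
    assert conn.COHERENCE_3HZ.nu0 == 10
    assert len(conn.COHERENCE_3HZ.centers) == 8


def test_identical_signals_fully_coherent(rng):
    x = rng.standard_normal(400)
    msc, f, p = conn.coherence_test(x, x, 200.0)
    assert np.all(msc > 0.999)
    assert np.all(p < 1e-6)


def test_coherence_type_one_error_rate(rng):
    fs, n_trials = 200.0, 1200
    rejections = 0
    for _ in range(n_trials):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        _, _, p = conn.coherence_test(x, y, fs, conn.COHERENCE_5HZ)
        rejections += int(p[1] < 0.05)  # 8.5 Hz band
    rate = rejections / n_trials
    assert rate == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# WPLI
# ---------------------------------------------------------------------------

def _alpha_pair(rng, n_epochs, fs, phase_lag, noise=0.05):
    """Coupled 10 Hz pair with a fixed phase offset."""
    t = np.arange(int(2 * fs)) / fs
    xs, ys = [], []
    for _ in range(n_epochs):
        phi = rng.uniform(0, 2 * np.pi)
        xs.append(np.sin(2 * np.pi * 10 * t + phi) + noise * rng.standard_normal(t.size))
        ys.append(np.sin(2 * np.pi * 10 * t + phi + phase_lag) + noise * rng.standard_normal(t.size))
    return np.array(xs), np.array(ys)


def test_wpli_quarter_cycle_lag_is_maximal(rng):
    x, y = _alpha_pair(rng, 20, 200.0, np.pi / 2)
    assert conn.wpli(x, y, 200.0) > 0.95


def test_wpli_zero_lag_coupling_suppressed(rng):
    x, y = _alpha_pair(rng, 20, 200.0, 0.0)
    assert conn.wpli(x, y, 200.0) < 0.3


def test_wpli_bounded_and_scale_invariant(rng):
    x = rng.standard_normal((8, 400))
    y = rng.standard_normal((8, 400))
    v = conn.wpli(x, y, 200.0)
    assert 0.0 <= v <= 1.0
    assert conn.wpli(3.7 * x, 0.2 * y, 200.0) == pytest.approx(v, rel=1e-9)


def test_wpli_matches_direct_formula(rng):
    from scipy.signal.windows import dpss

    fs = 200.0
    x = rng.standard_normal((3, 400))
    y = rng.standard_normal((3, 400))
    v = conn.wpli(x, y, fs, band=(8.0, 12.0))
    tapers = dpss(400, 3.0, Kmax=5)
    freqs = np.fft.rfftfreq(400, 1 / fs)
    sel = (freqs >= 8.0) & (freqs <= 12.0)
    ims = []
    for e in range(3):
        for k in range(5):
            X = np.fft.rfft(tapers[k] * x[e])[sel]
            Y = np.fft.rfft(tapers[k] * y[e])[sel]
            ims.extend(np.imag(X * np.conj(Y)))
    ims = np.array(ims)
    assert v == pytest.approx(abs(ims.mean()) / np.abs(ims).mean(), rel=1e-9)


def test_wpli_band_beyond_nyquist_rejected(rng):
    with pytest.raises(ValueError, match="Nyquist"):
        conn.wpli(rng.standard_normal((2, 400)), rng.standard_normal((2, 400)),
                  200.0, band=(90.0, 120.0))


def test_wpli_zero_imaginary_part_defined_as_zero():
    x = np.tile(np.sin(2 * np.pi * 10 * np.arange(400) / 200.0), (2, 1))
    assert conn.wpli(x, x, 200.0) == 0.0
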