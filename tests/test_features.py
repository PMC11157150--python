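import numpy as np
import pytest

from conftest import centered_from_arrays
from heatacc.features import (
    DEFAULT_ODBA_WINDOW,
    FEATURE_COLUMNS,
    feature_matrix,
    feature_vector,
    freq_features,
    odba,
    time_features,
)

FS = 33.3
N = 110


# ---------------------------------------------------------------------------
# independent oracles


def dft_oracle(series, fs):
    """Brute-force DFT spectral features (direct O(n^2) sum, DC excluded)."""
    x = np.asarray(series, float)
    x = x - x.mean()
    n = len(x)
    ks = np.arange(1, n // 2 + 1)
    mags = np.array(
        [abs(sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n))) for k in ks]
    )
    if mags.sum() <= 0:
        return 0.0, 0.0, 0.0
    k = int(np.argmax(mags))
    p = mags / mags.sum()
    nz = p[p > 0]
    ent = -(nz * np.log(nz)).sum() / np.log(len(mags))
    return ks[k] * fs / n, 2 * mags[k] / n, ent


def odba_oracle(x, y, z, window):
    """Double-loop ODBA: truncated centered running mean per axis."""
    n = len(x)
    left, right = (window - 1) // 2, window // 2
    total = 0.0
    for i in range(n):
        for arr in (x, y, z):
            lo, hi = max(0, i - left), min(n, i + right + 1)
            static = sum(arr[j] for j in range(lo, hi)) / (hi - lo)
            total += abs(arr[i] - static)
    return total / n


# ---------------------------------------------------------------------------
# time domain


class TestTimeFeatures:
    def test_constant_series(self):
        assert time_features([7.0] * 10) == (7, 0, 0, 7, 7, 0)

    def test_plus_minus_one(self):
        m, v, s, mx, mn, rg = time_features([-1.0, 1.0])
        assert (m, v, s, mx, mn, rg) == (0, 1, 1, 1, -1, 2)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 50, 60)
        fa, fb = time_features(a), time_features(-a)
        assert fa[1] == pytest.approx(fb[1])  # variance
        assert fa[2] == pytest.approx(fb[2])  # sd
        assert fa[5] == pytest.approx(fb[5])  # range

    def test_population_divisor(self):
        # var([0, 2]) = 1 with N divisor (1/N * sum sq dev), not 2
        assert time_features([0.0, 2.0])[1] == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_features([1.0])


# ---------------------------------------------------------------------------
# frequency domain


class TestFreqFeatures:
    def test_pure_sine_frequency_within_one_bin(self):
        t = np.arange(N) / FS
        fm, _, _ = freq_features(200 * np.sin(2 * np.pi * 2.0 * t), FS)
        assert abs(fm - 2.0) <= FS / N  # one bin width ~0.303 Hz

    def test_bin_centered_sine_amplitude_recovered(self):
        # an integer number of cycles avoids leakage, so freqamp ~ amplitude
        f = 7 * FS / N
        t = np.arange(N) / FS
        fm, fa, _ = freq_features(200 * np.sin(2 * np.pi * f * t), FS)
        assert fm == pytest.approx(f)
        assert fa == pytest.approx(200, rel=1e-6)

    def test_constant_series_degenerates_to_zero(self):
        assert freq_features([5.0] * 16, FS) == (0.0, 0.0, 0.0)

    def test_two_tone_entropy_exceeds_single_tone(self):
        t = np.arange(N) / FS
        single = 100 * np.sin(2 * np.pi * 2 * t)
        double = single + 100 * np.sin(2 * np.pi * 8 * t)
        assert freq_features(double, FS)[2] > freq_features(single, FS)[2]

    def test_matches_brute_force_dft_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            series = rng.normal(0, 100, 32)
            got = freq_features(series, FS)
            want = dft_oracle(series, FS)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1], rel=1e-9)
            assert got[2] == pytest.approx(want[2], rel=1e-9)

    def test_entropy_within_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            e = freq_features(rng.normal(0, 100, N), FS)[2]
            assert 0.0 <= e <= 1.0

    def test_white_noise_entropy_exceeds_pure_tone(self):
        """Unpredictable signals spread spectral mass; tones concentrate it."""
        rng = np.random.default_rng(10)
        t = np.arange(N) / FS
        tone_e = freq_features(100 * np.sin(2 * np.pi * 3 * t), FS)[2]
        noise_es = [freq_features(rng.normal(0, 100, N), FS)[2] for _ in range(100)]
        assert min(noise_es) > tone_e


# ---------------------------------------------------------------------------
# ODBA


class TestOdba:
    def test_constant_burst_is_zero(self):
        b = centered_from_arrays([100] * N, [-50] * N, [500] * N)
        assert odba(b) == pytest.approx(0.0)

    def test_single_spike_hand_computed(self):
        # x = [0, 0, 4, 0], window 4 (1 left / 2 right, truncated at edges):
        # statics are [4/3, 1, 4/3, 2], residuals [4/3, 1, 8/3, 2], mean 7/4
        b = centered_from_arrays([0, 0, 4, 0], [0] * 4, [0] * 4)
        assert odba(b, window=4) == pytest.approx(1.75)

    def test_default_window_is_fifth_of_burst(self):
        assert DEFAULT_ODBA_WINDOW == 110 // 5 == 22

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(23, 111))
            x, y, z = (rng.integers(-2048, 2048, n) for _ in range(3))
            b = centered_from_arrays(x, y, z)
            assert odba(b, 22) == pytest.approx(odba_oracle(x, y, z, 22), abs=1e-9)

    def test_window_larger_than_burst_rejected(self):
        b = centered_from_arrays([0] * 10, [0] * 10, [0] * 10)
        with pytest.raises(ValueError):
            odba(b, window=11)


# ---------------------------------------------------------------------------
# the assembled vector


class TestFeatureVector:
    def test_exactly_19_features(self):
        assert len(FEATURE_COLUMNS) == 19  # 2 channels x (6 + 3) + odba

    def test_constant_burst(self):
        b = centered_from_arrays([100] * N, [0] * N, [500] * N)
        fv = feature_vector(b)
        assert fv["x_mean"] == 100 and fv["yz_mean"] == 500
        for key in ("x_variance", "x_freqmain", "x_entropy", "odba", "yz_range"):
            assert fv[key] == 0

    def test_yz_features_invariant_to_collar_rotation(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 200, N)
        z = rng.normal(500, 200, N)
        x = rng.normal(0, 100, N)
        base = feature_vector(centered_from_arrays(x, y, z))
        theta = 1.234
        yr = y * np.cos(theta) - z * np.sin(theta)
        zr = y * np.sin(theta) + z * np.cos(theta)
        rot = feature_vector(centered_from_arrays(x, yr, zr))
        for key in FEATURE_COLUMNS:
            if key.startswith("yz_"):
                assert rot[key] == pytest.approx(base[key], rel=1e-6, abs=1e-6)

    def test_scaling_laws(self):
        """Scaling counts by k scales linear features by k, variance by k^2,
        and leaves freqmain/entropy unchanged."""
        rng = np.random.default_rng(7)
        t = np.arange(N) / FS
        x = 100 * np.sin(2 * np.pi * 1.5 * t) + rng.normal(0, 30, N)
        y = rng.normal(0, 80, N)
        z = rng.normal(400, 60, N)
        base = feature_vector(centered_from_arrays(x, y, z))
        k = 3.0
        scaled = feature_vector(centered_from_arrays(k * x, k * y, k * z))
        for ch in ("x", "yz"):
            for lin in ("mean", "sd", "max", "min", "range", "freqamp"):
                assert scaled[f"{ch}_{lin}"] == pytest.approx(
                    k * base[f"{ch}_{lin}"], rel=1e-6, abs=1e-6
                )
            assert scaled[f"{ch}_variance"] == pytest.approx(
                k**2 * base[f"{ch}_variance"], rel=1e-6
            )
            assert scaled[f"{ch}_freqmain"] == base[f"{ch}_freqmain"]
            assert scaled[f"{ch}_entropy"] == pytest.approx(base[f"{ch}_entropy"], rel=1e-9)
        assert scaled["odba"] == pytest.approx(k * base["odba"], rel=1e-9)

    def test_matrix_matches_scalar_path(self):
        rng = np.random.default_rng(12)
        bursts = [
            centered_from_arrays(
                rng.integers(-2048, 2048, N),
                rng.integers(-2048, 2048, N),
                rng.integers(-2048, 2048, N),
            )
            for _ in range(6)
        ]
        mat = feature_matrix(bursts)
        for i, b in enumerate(bursts):
            fv = feature_vector(b)
            for key, val in fv.items():
                assert mat.iloc[i][key] == pytest.approx(val, rel=1e-9, abs=1e-9)

    def test_matrix_column_contract(self):
        mat = feature_matrix([])
        assert list(mat.columns) == ["individual_id", "timestamp", *FEATURE_COLUMNS]
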