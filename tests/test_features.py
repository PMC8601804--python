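import math

import numpy as np
import pytest
import scipy.signal

from cryclass import synthcry
from cryclass.features import (
    FeatureConfig,
    NoCryDetectedError,
    average,
    bandwidth,
    delta_mfcc,
    extract_features,
    feature_family,
    formants_lpc,
    lpc_coefficients,
    lpcc,
    lpcc_from_lpc,
    magnitude,
    mel_filterbank,
    mfcc,
    peak_valley,
    pitch_autocorr,
    subband_bins,
    variance,
    zero_crossing_rate,
)
from cryclass.preprocess import AudioClip


class TestTimeDomain:
    @pytest.mark.parametrize(
        "fn, x, expected",
        [
            (magnitude, [1, -1, 2], 4.0),
            (magnitude, [0, 0, 0], 0.0),
            (magnitude, [0.5] * 8, 4.0),
            (average, [1, -1, 2], 2 / 3),
            (average, [0, 0], 0.0),
            (average, [3.5, 3.5], 3.5),
            (variance, [1, -1, 2], 14 / 9),
            (variance, [7, 7, 7], 0.0),
            (variance, [1, -1], 1.0),
        ],
    )
    def test_hand_values(self, fn, x, expected):
        assert fn(np.array(x, float)) == pytest.approx(expected)

    def test_zcr_alternating(self):
        assert zero_crossing_rate(np.array([1.0, -1, 1, -1, 1, -1])) == 1.0

    def test_zcr_constant(self):
        assert zero_crossing_rate(np.ones(10)) == 0.0

    def test_zcr_one_sine_period_eight_samples(self):
        # samples: 0, .707, 1, .707, 0, -.707, -1, -.707; the zero at i=4
        # inherits the previous (+) sign, the leading zero counts against
        # the first nonzero sample -> 2 sign changes over 7 steps
        x = np.sin(2 * np.pi * np.arange(8) / 8)
        assert zero_crossing_rate(x) == pytest.approx(2 / 7)


class TestBandwidth:
    def test_single_bin_zero_spread(self):
        spec = np.zeros(16)
        spec[5] = 3.0
        assert bandwidth(spec) == 0.0

    def test_two_equal_bins(self):
        spec = np.zeros(8)
        spec[0] = spec[2] = 1.0
        assert bandwidth(spec) == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        spec = rng.uniform(0, 2, size=129)
        w = spec**2
        fc = sum(i * w[i] for i in range(len(w))) / w.sum()
        fb = sum(w[i] * (i - fc) ** 2 for i in range(len(w))) / w.sum()
        assert bandwidth(spec) == pytest.approx(fb, rel=1e-12)

    def test_all_zero_spectrum_is_zero(self):
        assert bandwidth(np.zeros(10)) == 0.0


class TestPeakValley:
    def test_sorted_mean_hand_case(self):
        peaks, valleys = peak_valley(np.array([4.0, 3, 2, 1]), [(0, 4)], alpha=0.5)
        assert peaks[0] == pytest.approx(math.log(3.5))
        assert valleys[0] == pytest.approx(math.log(1.5))

    def test_constant_subband(self):
        peaks, valleys = peak_valley(np.full(6, 2.5), [(0, 6)], alpha=0.2)
        assert peaks[0] == valleys[0] == pytest.approx(math.log(2.5))

    def test_alpha_one_full_band_mean(self):
        spec = np.array([1.0, 2, 3, 6])
        peaks, valleys = peak_valley(spec, [(0, 4)], alpha=1.0)
        assert peaks[0] == valleys[0] == pytest.approx(math.log(3.0))

    def test_empty_subband_rejected(self):
        with pytest.raises(ValueError):
            peak_valley(np.ones(4), [(2, 2)], alpha=0.5)

    def test_subband_partition_covers_spectrum(self):
        bands = subband_bins(513, (0.0, 1 / 32, 1 / 8, 1 / 2, 1.0))
        assert bands[0][0] == 0 and bands[-1][1] == 513
        for (a, b), (c, d) in zip(bands, bands[1:]):
            assert b == c


class TestPitch:
    def test_pure_sine_441k(self):
        fs = 44100
        t = np.arange(4096) / fs
        f0 = pitch_autocorr(np.sin(2 * np.pi * 400 * t), fs)
        assert f0 == pytest.approx(400, abs=4)

    def test_white_noise_unvoiced(self):
        rng = np.random.default_rng(3)
        assert pitch_autocorr(rng.normal(size=4096), 44100) == 0.0

    def test_pulse_train(self):
        fs = 44100
        period = round(fs / 300)
        x = np.zeros(4096)
        x[::period] = 1.0
        f0 = pitch_autocorr(x, fs)
        assert f0 == pytest.approx(fs / period, abs=3)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            pitch_autocorr(np.ones(50), 44100)


class TestFormants:
    fs = 16000

    def _resonate(self, freqs, n=8192, r=0.98, seed=0):
        x = np.random.default_rng(seed).normal(size=n)
        for f in freqs:
            b, a = [1.0], [1.0, -2 * r * np.cos(2 * np.pi * f / self.fs), r * r]
            x = scipy.signal.lfilter(b, a, x)
        return x

    def test_single_resonator(self):
        f = formants_lpc(self._resonate([1000]), self.fs)
        assert f[0] == pytest.approx(1000, abs=50)

    def test_two_resonators(self):
        f = formants_lpc(self._resonate([800, 2400]), self.fs)
        assert f[0] == pytest.approx(800, abs=75)
        assert f[1] == pytest.approx(2400, abs=75)

    def test_zero_frame_all_zero(self):
        np.testing.assert_array_equal(formants_lpc(np.zeros(512), self.fs), np.zeros(6))

    def test_found_formants_ascending(self):
        f = formants_lpc(self._resonate([600, 1800, 3500]), self.fs)
        nz = f[f > 0]
        assert np.all(np.diff(nz) > 0)


class TestLpcc:
    def test_recursion_unrolled_p2(self):
        # with prediction coefficients (a1, 0): c1 = a1, c2 = a1^2 / 2
        a1 = 0.8
        c = lpcc_from_lpc(np.array([a1, 0.0]), 2)
        assert c[0] == pytest.approx(a1)
        assert c[1] == pytest.approx(a1**2 / 2)

    def test_zero_frame_zero_vector(self):
        np.testing.assert_array_equal(lpcc(np.zeros(256), 12), np.zeros(12))

    def test_ar2_process_recovery(self):
        a_true = np.array([1.1, -0.5])
        rng = np.random.default_rng(9)
        x = np.zeros(4096)
        e = rng.normal(size=4096)
        for n in range(2, 4096):
            x[n] = a_true[0] * x[n - 1] + a_true[1] * x[n - 2] + e[n]
        a_est = lpc_coefficients(x, 2)
        np.testing.assert_allclose(a_est, a_true, rtol=0.05)
        c_est = lpcc(x, p=4, lpc_order=2)
        c_true = lpcc_from_lpc(a_true, 4)
        np.testing.assert_allclose(c_est, c_true, rtol=0.05, atol=0.01)


class TestMfcc:
    fs = 16000

    def test_flat_filterbank_energies_give_zero(self):
        # a spectrum whose filterbank output is constant puts everything in
        # DCT coefficient 0, which is excluded; build such a spectrum by
        # non-negative least squares against a constant target
        import scipy.optimize

        fb = mel_filterbank(26, 257, self.fs)
        power, residual = scipy.optimize.nnls(fb, np.ones(26))
        assert residual < 1e-9
        np.testing.assert_allclose(mfcc(np.sqrt(power), self.fs), 0.0, atol=1e-9)

    def test_power_scaling_only_shifts_coefficient_zero(self):
        rng = np.random.default_rng(2)
        spec = rng.uniform(0.1, 2.0, size=257)
        np.testing.assert_allclose(
            mfcc(spec, self.fs), mfcc(10.0 * spec, self.fs), atol=1e-10
        )

    def test_n_mels_must_cover_order(self):
        with pytest.raises(ValueError):
            mfcc(np.ones(257), self.fs, n_mels=8, p=12)


class TestDeltaMfcc:
    def test_constant_track_zero(self):
        np.testing.assert_array_equal(delta_mfcc(np.ones((10, 3))), np.zeros((10, 3)))

    def test_linear_ramp_interior_slope(self):
        v = 0.7
        track = v * np.arange(20)[:, None] * np.ones((1, 4))
        deltas = delta_mfcc(track, window=2)
        np.testing.assert_allclose(deltas[2:-2], v, atol=1e-12)

    def test_single_frame_zero(self):
        np.testing.assert_array_equal(delta_mfcc(np.array([[1.0, 2.0]])), [[0.0, 0.0]])


class TestExtractFeatures:
    def test_clip_pitch_mean_in_class_band(self):
        config = synthcry.preset("separable")
        sc = synthcry.generate_clip(config, "sleep", 21)
        fm = extract_features(sc.clip)
        lo, hi = config.classes["sleep"].f0_range
        assert lo * 0.97 <= fm.X["pitch_mean"].iloc[0] <= hi * 1.03

    def test_silence_only_clip_rejected(self):
        clip = AudioClip(np.full(16000, 1e-9), 16000, label="sleep", source_id="quiet")
        clip.samples[0] = 1.0  # lone spike, no sustained unit
        with pytest.raises(NoCryDetectedError, match="quiet"):
            extract_features(clip)

    def test_deterministic(self):
        sc = synthcry.generate_clip(synthcry.preset("separable"), "hunger", 5)
        a = extract_features(sc.clip)
        b = extract_features(sc.clip)
        assert a.X.equals(b.X)

    def test_time_domain_invariant_to_mel_config(self):
        sc = synthcry.generate_clip(synthcry.preset("separable"), "hunger", 6)
        a = extract_features(sc.clip, FeatureConfig(n_mels=26))
        b = extract_features(sc.clip, FeatureConfig(n_mels=30))
        for col in ("magnitude_mean", "average_mean", "variance_mean", "zcr_mean", "pitch_mean"):
            assert a.X[col].iloc[0] == b.X[col].iloc[0]

    def test_no_missing_values_and_stable_schema(self, small_dataset):
        _, _, fm = small_dataset
        assert not fm.X.isna().any().any()
        assert fm.schema[:5] == [
            "magnitude_mean", "magnitude_std", "average_mean", "average_std",
            "variance_mean",
        ]


@pytest.mark.parametrize(
    "column, family",
    [
        ("mfcc_3_mean", "mfcc"),
        ("dmfcc_12_std", "dmfcc"),
        ("pitch_mean", "pitch"),
        ("peak_2", "peak"),
        ("zcr_std", "zcr"),
        ("formant_6_mean", "formant"),
    ],
)
def test_feature_family_mapping(column, family):
    assert feature_family(column) == family
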