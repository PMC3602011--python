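"""Upper-bound regression, vocal deviation, and consistency scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.optimize import minimize_scalar

from trillgauge import audio_features as af
from trillgauge import performance as perf
from trillgauge.synthetic_data import TrillGroundTruth, simulate_trill_cloud, synth_trill

SR = 48000


class TestUpperBoundRegression:
    def test_collinear_bin_maxima_recovered_exactly(self, rng):
        # random cloud sits >= 50 Hz under the line; one point exactly on the
        # line at each bin's left edge is then the guaranteed bin maximum
        T = rng.uniform(2.2, 15.8, 300)
        B = -100.0 * T + 5000.0 - rng.uniform(50, 800, 300)
        for k in range(1, 8):
            T = np.append(T, 2.0 * k)
            B = np.append(B, -100.0 * (2.0 * k) + 5000.0)
        lim = perf.upper_bound_regression(T, B, bin_width=2.0)
        assert lim.slope == pytest.approx(-100.0, abs=1e-9)
        assert lim.intercept == pytest.approx(5000.0, abs=1e-6)

    def test_identical_points_error(self):
        with pytest.raises(ValueError):
            perf.upper_bound_regression(np.full(50, 7.0), np.full(50, 3000.0))

    def test_too_few_bins_error(self, rng):
        T = rng.uniform(4, 6, 100)  # one or two occupied bins at width 2
        B = rng.uniform(1000, 4000, 100)
        with pytest.raises(ValueError, match="bins"):
            perf.upper_bound_regression(T, B, bin_width=2.0)

    def test_cloud_recovery_single_seed(self):
        T, B = simulate_trill_cloud(500, rng=np.random.default_rng(5))
        lim = perf.upper_bound_regression(T, B, bin_width=2.0)
        assert lim.slope == pytest.approx(-168.50, rel=0.15)
        assert lim.intercept == pytest.approx(6019.0, rel=0.10)


def brute_force_distance(T, B, a, b):
    """Nearest-point distance to the line by 1-D minimisation over the line."""
    f = lambda t: np.hypot(t - T, a * t + b - B)
    res = minimize_scalar(f, bracket=(T - 100, T + 100), options={"xtol": 1e-14})
    return res.fun


class TestVocalDeviation:
    def test_point_on_line_is_zero(self):
        lim = perf.PerformanceLimit(-168.5, 6019.0, 6, 2.0)
        assert perf.vocal_deviation(10.0, -168.5 * 10 + 6019.0, lim) == pytest.approx(0.0)

    def test_paper_scale_example(self):
        lim = perf.PerformanceLimit(-168.5, 6019.0, 6, 2.0)
        assert perf.vocal_deviation(10.0, 2000.0, lim) == pytest.approx(13.851, abs=1e-3)

    def test_sign_negative_above_line(self):
        lim = perf.PerformanceLimit(-168.5, 6019.0, 6, 2.0)
        assert perf.vocal_deviation(5.0, 6019.0 - 168.5 * 5 + 1.0, lim) < 0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        a=hst.floats(-400, -20),
        b=hst.floats(2000, 9000),
        T=hst.floats(2, 20),
        B=hst.floats(200, 8000),
    )
    def test_deviation_properties(self, a, b, T, B):
        """Sign follows the side of the line; magnitude never exceeds the
        vertical gap; time-shifting a trill cannot change its deviation."""
        lim = perf.PerformanceLimit(a, b, 6, 2.0)
        d = perf.vocal_deviation(T, B, lim)
        gap = a * T + b - B
        assert np.sign(d) == np.sign(gap) or gap == 0
        assert abs(d) <= abs(gap) + 1e-9

    def test_matches_brute_force_nearest_point(self, rng):
        for _ in range(200):
            a = rng.uniform(-400, -20)
            b = rng.uniform(2000, 9000)
            T = rng.uniform(2, 20)
            B = rng.uniform(200, 8000)
            lim = perf.PerformanceLimit(a, b, 6, 2.0)
            d = perf.vocal_deviation(T, B, lim)
            assert abs(abs(d) - brute_force_distance(T, B, a, b)) < 1e-9


def _syllable_spec(seed=0, jitter=0.0, f0=5000.0, f1=3500.0):
    from trillgauge.synthetic_data import SyllableSpec, synth_syllable

    w = synth_syllable(
        SyllableSpec(f0, f1, 0.06), SR, jitter_sd=jitter,
        rng=np.random.default_rng(seed),
    )
    freqs, _, mag = af.spectrogram(w, SR, af.CORRELATION_PRESET)
    return freqs, mag


class TestSyllableXcorr:
    def test_identical_syllables_score_one(self):
        freqs, mag = _syllable_spec()
        s = perf.syllable_xcorr(mag, mag, freqs, freq_bounds=(3500, 5000))
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_bands_near_zero(self):
        freqs, a = _syllable_spec(f0=3000, f1=2500)
        _, b = _syllable_spec(f0=9000, f1=8500)
        s = perf.syllable_xcorr(a, b, freqs, freq_bounds=(2000, 10000))
        assert s < 0.05

    def test_frequency_shift_lowers_score(self):
        freqs, a = _syllable_spec(f0=5000, f1=3500)
        _, b = _syllable_spec(f0=5500, f1=4000)
        self_score = perf.syllable_xcorr(a, a, freqs, freq_bounds=(3000, 6000))
        shifted = perf.syllable_xcorr(a, b, freqs, freq_bounds=(3000, 6000))
        assert shifted < self_score

    def test_symmetry_and_bounds(self, rng):
        freqs, a = _syllable_spec(seed=1, jitter=0.05)
        _, b = _syllable_spec(seed=2, jitter=0.05)
        s1 = perf.syllable_xcorr(a, b, freqs)
        s2 = perf.syllable_xcorr(b, a, freqs)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert 0.0 <= s1 <= 1.0

    def test_grid_mismatch_errors(self):
        freqs, a = _syllable_spec()
        with pytest.raises(ValueError):
            perf.syllable_xcorr(a, a[:-5], freqs)

    def test_all_masked_scores_zero_with_warning(self):
        freqs = np.arange(0.0, 513.0) * 46.875
        a = np.zeros((513, 10))
        a[50:60, :] = 1.0  # energy far below the bounded band
        with pytest.warns(UserWarning):
            s = perf.syllable_xcorr(a, a, freqs, freq_bounds=(20000, 21000))
        assert s == 0.0


def _trill_specs(jitter, seed, snr=None, n=6):
    gt = TrillGroundTruth(
        male_id="M", year=2009, trill_type=1, rate=8.0, bandwidth=1800.0,
        pitch=6000.0, jitter_sd=jitter, n_syllables=n, time_in_song=0.0,
    )
    wave, ann = synth_trill(gt, SR, rng=np.random.default_rng(seed), snr_db=snr)
    specs, freqs = [], None
    for _, r in ann.iterrows():
        seg = wave[int(r.begin_s * SR): int(r.end_s * SR)]
        freqs, _, mag = af.spectrogram(seg, SR, af.CORRELATION_PRESET)
        specs.append(mag)
    return specs, freqs, (ann.low_hz.min(), ann.high_hz.max()), wave, ann


class TestTrillConsistency:
    def test_identical_syllables_give_exactly_one(self):
        specs, freqs, bounds, _, _ = _trill_specs(jitter=0.0, seed=0, snr=None)
        c = perf.trill_consistency(specs, freqs, freq_bounds=bounds)
        assert c == 1.0

    def test_mean_of_pairwise_scores(self):
        # 3 syllables -> consistency is the arithmetic mean of the 3 pair scores
        specs, freqs, bounds, _, _ = _trill_specs(jitter=0.06, seed=3, snr=30, n=3)
        m = perf.pairwise_xcorr_matrix(specs, freqs, freq_bounds=bounds)
        expected = (m[0, 1] + m[0, 2] + m[1, 2]) / 3
        c = perf.trill_consistency(specs, freqs, freq_bounds=bounds)
        assert c == pytest.approx(expected, abs=1e-12)

    def test_single_syllable_errors(self):
        specs, freqs, bounds, _, _ = _trill_specs(jitter=0.0, seed=0)
        with pytest.raises(ValueError):
            perf.trill_consistency(specs[:1], freqs)

    def test_out_of_band_noise_changes_little(self):
        # bounding at +/-200 Hz suppresses interference outside the trill band
        specs, freqs, bounds, wave, ann = _trill_specs(jitter=0.03, seed=4, snr=30)
        c_clean = perf.trill_consistency(specs, freqs, freq_bounds=bounds)
        rng = np.random.default_rng(9)
        noisy = []
        for _, r in ann.iterrows():
            seg = wave[int(r.begin_s * SR): int(r.end_s * SR)].copy()
            t = np.arange(seg.size) / SR
            # strong tone far outside the bounded band
            seg += 0.5 * np.sin(2 * np.pi * 15000 * t + rng.uniform(0, 6))
            _, _, mag = af.spectrogram(seg, SR, af.CORRELATION_PRESET)
            noisy.append(mag)
        c_noisy = perf.trill_consistency(noisy, freqs, freq_bounds=bounds)
        assert abs(c_noisy - c_clean) < 0.01


class TestConsistencyTransform:
    @pytest.mark.parametrize(
        "c,expected", [(0.0, 0.0), (0.9, 2.302585), (0.5, 0.693147)]
    )
    def test_values(self, c, expected):
        assert perf.consistency_transform(c) == pytest.approx(expected, abs=1e-6)

    def test_capped_at_one(self):
        out = perf.consistency_transform(1.0)
        assert np.isfinite(out)
        assert out == pytest.approx(-np.log(1e-6))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            perf.consistency_transform(1.2)
        with pytest.raises(ValueError):
            perf.consistency_transform(-0.1)
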