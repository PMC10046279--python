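"""Feature extraction: bandpass, peak detection, and the 43-feature registry
checked feature-by-feature against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import ranksums

from ecgqc.features import (
    N_FEATURES,
    bandpass,
    detect_peaks,
    dtw_distance,
    extract_features,
    select_k_best,
    stft_magnitude,
    subsegments,
)
from ecgqc.segment import ECGSegment
from ecgqc.synth import SegmentSpec, generate_dataset, generate_segment

from . import oracles
from .conftest import make_segment


def sine_segment(freq_hz, fs=250, duration=20.0):
    t = np.arange(int(fs * duration)) / fs
    return make_segment(np.sin(2 * np.pi * freq_hz * t), fs_hz=fs)


class TestBandpass:
    def test_passband_tone_passes(self):
        seg = sine_segment(4.0)
        out = bandpass(seg)
        ratio = np.std(out.values[500:-500]) / np.std(seg.values[500:-500])
        assert 20 * np.log10(ratio) > -3.0

    def test_deep_stopband_attenuation(self):
        seg = sine_segment(0.05)
        out = bandpass(seg)
        ratio = np.std(out.values) / np.std(seg.values)
        assert 20 * np.log10(ratio) < -20.0

    def test_zero_in_zero_out(self):
        out = bandpass(make_segment(np.zeros(5000)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(sine_segment(4.0), 8.0, 0.5)
        with pytest.raises(ValueError):
            bandpass(sine_segment(4.0), 0.5, 300.0)


class TestDetectPeaks:
    def test_beat_count_on_clean_segment(self, clean_segment):
        assert abs(len(detect_peaks(clean_segment)) - 20) <= 1

    def test_flat_segment_has_no_peaks(self):
        assert len(detect_peaks(make_segment(np.zeros(5000)))) == 0

    def test_negation_finds_troughs(self):
        # polarity-inverted lead: R deflections point down, so the detector
        # sees them only on the negated signal
        inv = generate_segment(
            SegmentSpec(heart_rate_bpm=60, qrs_amplitude_mv=-1.0, seed=2)
        )
        # the detector returns peaks, never troughs: on the inverted lead it
        # cannot reach the -1 mV R deflections
        plain = detect_peaks(inv)
        assert np.all(plain.amplitudes > -0.3)
        neg = inv.with_values(-inv.values)
        peaks_neg = detect_peaks(neg)
        assert abs(len(peaks_neg) - 20) <= 1
        # detected as peaks of -x, they are the troughs of the original
        assert np.all(inv.values[peaks_neg.indices] < -0.3)

    def test_amplitudes_from_original_signal(self, clean_segment):
        pk = detect_peaks(clean_segment)
        np.testing.assert_array_equal(pk.amplitudes, clean_segment.values[pk.indices])


class TestSubsegments:
    def test_default_split(self, clean_segment):
        parts = subsegments(clean_segment)
        assert len(parts) == 5
        assert all(len(p) == 1000 for p in parts)
        np.testing.assert_array_equal(np.concatenate(parts), clean_segment.values)

    def test_whole_segment_window(self, clean_segment):
        parts = subsegments(clean_segment, 20.0)
        assert len(parts) == 1 and len(parts[0]) == 5000

    def test_non_divisor_rejected(self, clean_segment):
        with pytest.raises(ValueError):
            subsegments(clean_segment, 3.0)


@pytest.fixture(scope="module")
def oracle_segment():
    """12-s / 50 Hz contaminated beat train: 3 subsegments, small enough for
    the quadratic brute-force oracles."""
    return generate_segment(
        SegmentSpec(
            heart_rate_bpm=66, fs_hz=50, duration_s=12.0,
            noise_sigma_mv=0.1, wander_amplitude_mv=0.5, seed=5,
        )
    )


@pytest.fixture(scope="module")
def fv(oracle_segment):
    return extract_features(oracle_segment)


@pytest.fixture(scope="module")
def x(oracle_segment):
    return oracle_segment.values


class TestFeatureOracles:
    """Every registry feature against a direct formula evaluation."""

    def test_vector_shape_and_validity(self, fv):
        assert len(fv.values) == N_FEATURES == 43
        assert np.all(np.isfinite(fv.values))

    def test_slope_features(self, fv, x):
        m, s = oracles.mean_std(oracles.slopes(list(x)))
        np.testing.assert_allclose(fv["mean(slopes)"], m, rtol=1e-9)
        np.testing.assert_allclose(fv["stddev(slopes)"], s, rtol=1e-9)

    def test_peak_amplitude_features(self, fv, oracle_segment, x):
        pk = detect_peaks(oracle_segment)
        amps = list(x[pk.indices])
        m, s = oracles.mean_std(amps)
        z = [(a - m) / s for a in amps]
        np.testing.assert_allclose(fv["max(zscore(peakamplitude))"], max(z), rtol=1e-9)
        np.testing.assert_allclose(fv["max(peakamplitude)"], max(amps), rtol=1e-9)

        neg = oracle_segment.with_values(-x)
        pkn = detect_peaks(neg)
        amps_n = list(-x[pkn.indices])
        mn, sn = oracles.mean_std(amps_n)
        zn = [(a - mn) / sn for a in amps_n]
        np.testing.assert_allclose(
            fv["max(zscore(peakamplitude_neg))"], max(zn), rtol=1e-9
        )
        np.testing.assert_allclose(
            fv["min(zscore(peakamplitude_neg))"], min(zn), rtol=1e-9
        )
        np.testing.assert_allclose(fv["max(peakamplitude_neg)"], max(amps_n), rtol=1e-9)

    def test_per_block_peak_spread_features(self, fv, oracle_segment, x):
        fs = oracle_segment.fs_hz
        pk = detect_peaks(oracle_segment)
        pkn = detect_peaks(oracle_segment.with_values(-x))
        means, maxes, mins = [], [], []
        for blk in range(3):
            lo, hi = blk * 4 * fs, (blk + 1) * 4 * fs
            in_b = [a for i, a in zip(pk.indices, pk.amplitudes) if lo <= i < hi]
            if in_b:
                means.append(sum(in_b) / len(in_b))
                maxes.append(max(in_b))
            in_bn = [x[i] for i in pkn.indices if lo <= i < hi]
            if in_bn:
                mins.append(min(in_bn))
        np.testing.assert_allclose(
            fv["stddev(mean(peakamplitude))"], oracles.mean_std(means)[1], rtol=1e-9
        )
        np.testing.assert_allclose(
            fv["stddev(max(peakamplitude))"], oracles.mean_std(maxes)[1], rtol=1e-9
        )
        np.testing.assert_allclose(
            fv["stddev(min(peakminamplitude))"], oracles.mean_std(mins)[1], rtol=1e-9
        )

    @pytest.mark.parametrize("suffix,sign", [("", 1.0), ("_neg", -1.0)])
    def test_autocorrelation_features(self, fv, x, oracle_segment, suffix, sign):
        pool = oracles.autocorr_pool(list(sign * x), oracle_segment.fs_hz)
        m, s = oracles.mean_std(pool)
        np.testing.assert_allclose(fv[f"mean(autocorr{suffix})"], m, rtol=1e-8)
        np.testing.assert_allclose(fv[f"stddev(autocorr{suffix})"], s, rtol=1e-8)

    @pytest.mark.parametrize("suffix,sign", [("", 1.0), ("_neg", -1.0)])
    def test_crosscorrelation_features(self, fv, x, oracle_segment, suffix, sign):
        pool = oracles.crosscorr_pool(list(sign * x), oracle_segment.fs_hz)
        m, s = oracles.mean_std(pool)
        np.testing.assert_allclose(fv[f"mean(crosscorr{suffix})"], m, rtol=1e-7)
        np.testing.assert_allclose(fv[f"stddev(crosscorr{suffix})"], s, rtol=1e-7)

    @pytest.mark.parametrize("suffix,sign", [("", 1.0), ("_neg", -1.0)])
    def test_moment_features(self, fv, x, oracle_segment, suffix, sign):
        blocks = oracles.blocks_of(list(sign * x), oracle_segment.fs_hz)
        skews = [v for v in (oracles.skew_of(b) for b in blocks) if v is not None]
        kurts = [v for v in (oracles.kurtosis_of(b) for b in blocks) if v is not None]
        np.testing.assert_allclose(
            fv[f"mean(skew{suffix})"], oracles.mean_std(skews)[0], rtol=1e-8
        )
        np.testing.assert_allclose(
            fv[f"stddev(skew{suffix})"], oracles.mean_std(skews)[1], rtol=1e-8
        )
        np.testing.assert_allclose(
            fv[f"mean(kurtosis{suffix})"], oracles.mean_std(kurts)[0], rtol=1e-8
        )
        np.testing.assert_allclose(
            fv[f"stddev(kurtosis{suffix})"], oracles.mean_std(kurts)[1], rtol=1e-8
        )

    @pytest.mark.parametrize("suffix,sign", [("", 1.0), ("_neg", -1.0)])
    def test_hurst_features(self, fv, x, oracle_segment, suffix, sign):
        blocks = oracles.blocks_of(list(sign * x), oracle_segment.fs_hz)
        hes = [v for v in (oracles.hurst_rs(b) for b in blocks) if v is not None]
        m, s = oracles.mean_std(hes)
        np.testing.assert_allclose(fv[f"mean(he{suffix})"], m, rtol=1e-6)
        np.testing.assert_allclose(fv[f"stddev(he{suffix})"], s, rtol=1e-6)

    @pytest.mark.parametrize("suffix,sign", [("", 1.0), ("_neg", -1.0)])
    def test_dtw_features(self, fv, x, oracle_segment, suffix, sign):
        pool = oracles.dtw_pool(sign * x, oracle_segment.fs_hz)
        m, s = oracles.mean_std(pool)
        np.testing.assert_allclose(fv[f"mean(dtw{suffix})"], m, rtol=1e-8)
        np.testing.assert_allclose(fv[f"stddev(dtw{suffix})"], s, rtol=1e-8)

    @pytest.mark.parametrize("suffix,sign", [("", 1.0), ("_neg", -1.0)])
    def test_maxpower_features(self, fv, x, oracle_segment, suffix, sign):
        pool = oracles.maxpower_pool(sign * x, oracle_segment.fs_hz)
        m, s = oracles.mean_std(pool)
        np.testing.assert_allclose(fv[f"mean(maxpower{suffix})"], m, rtol=1e-8)
        np.testing.assert_allclose(fv[f"stddev(maxpower{suffix})"], s, rtol=1e-8)

    def test_dominant_component_drift_features(self, fv, x, oracle_segment):
        powers, freqs = oracles.maxpower_freqs(x, oracle_segment.fs_hz)
        pdiffs = [powers[i + 1] - powers[i] for i in range(len(powers) - 1)]
        fdiffs = [freqs[i + 1] - freqs[i] for i in range(len(freqs) - 1)]
        np.testing.assert_allclose(
            fv["stddev(meanpowerdiff)"], oracles.mean_std(pdiffs)[1], rtol=1e-8
        )
        np.testing.assert_allclose(
            fv["stddev(meanfreqdiff)"], oracles.mean_std(fdiffs)[1], rtol=1e-8
        )

    def test_stft_features(self, fv, x):
        frames = oracles.stft_frames(list(x))
        allmag = [v for fr in frames for v in fr]
        m, s = oracles.mean_std(allmag)
        np.testing.assert_allclose(fv["mean(abs(stft))"], m, rtol=1e-8)
        np.testing.assert_allclose(fv["std(abs(stft))"], s, rtol=1e-8)
        ents = oracles.spectral_entropies(list(x))
        np.testing.assert_allclose(
            fv["stddev(se)"], oracles.mean_std(ents)[1], rtol=1e-8
        )


class TestFeatureProperties:
    def test_ramp_slopes(self):
        # linear ramp a*t: every first difference is a/fs
        fs, a = 250, 3.0
        t = np.arange(5000) / fs
        fv = extract_features(make_segment(a * t))
        np.testing.assert_allclose(fv["mean(slopes)"], a / fs, rtol=1e-9)
        np.testing.assert_allclose(fv["stddev(slopes)"], 0.0, atol=1e-12)

    def test_constant_signal_sentinels(self):
        fv = extract_features(make_segment(np.full(5000, 2.5)))
        assert not fv.is_valid("mean(autocorr)")
        assert fv["mean(autocorr)"] == 0.0
        assert not fv.is_valid("max(zscore(peakamplitude))")
        assert np.all(np.isfinite(fv.values))

    def test_negation_symmetry(self, oracle_segment):
        fv = extract_features(oracle_segment)
        fv_neg = extract_features(oracle_segment.with_values(-oracle_segment.values))
        # the _neg features of x are the plain features of -x and vice versa
        np.testing.assert_allclose(
            fv["max(peakamplitude_neg)"], fv_neg["max(peakamplitude)"], rtol=1e-9
        )
        np.testing.assert_allclose(
            fv["mean(skew_neg)"], fv_neg["mean(skew)"], rtol=1e-9
        )
        np.testing.assert_allclose(
            fv["mean(autocorr_neg)"], fv_neg["mean(autocorr)"], rtol=1e-9
        )
        np.testing.assert_allclose(
            fv["mean(dtw_neg)"], fv_neg["mean(dtw)"], rtol=1e-9
        )

    def test_determinism(self, clean_segment):
        a = extract_features(clean_segment)
        b = extract_features(clean_segment)
        np.testing.assert_array_equal(a.values, b.values)

    def test_clean_beats_have_higher_crosscorr_than_noisy(
        self, clean_segment, noisy_segment
    ):
        clean = extract_features(clean_segment)
        noisy = extract_features(noisy_segment)
        assert clean["mean(crosscorr)"] > noisy["mean(crosscorr)"]

    def test_noise_separates_slope_spread(self):
        # distribution of stddev(slopes) differs between quality classes
        segs = generate_dataset((50, 50, 0), seed=21)
        vals = np.array([extract_features(s)["stddev(slopes)"] for s in segs])
        stat = ranksums(vals[:50], vals[50:])
        assert stat.pvalue < 0.01


class TestDTWPrimitive:
    def test_matches_plain_dp(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=17), rng.normal(size=23)
        np.testing.assert_allclose(
            dtw_distance(a, b), oracles.dtw_plain(list(a), list(b)), rtol=1e-12
        )

    def test_identical_sequences_zero(self):
        a = np.arange(10.0)
        assert dtw_distance(a, a) == 0.0


class TestSelectKBest:
    def toy(self):
        # column 0 separates the classes perfectly; column 1 is noise
        X = np.array(
            [[0.0, 3.1], [0.1, -2.0], [0.05, 0.7],
             [1.0, 1.5], [0.9, -0.3], [1.1, 0.2]]
        )
        y = [0, 0, 0, 1, 1, 1]
        return X, y

    def test_identity_when_k_equals_n(self):
        X, y = self.toy()
        assert set(select_k_best(X, y, 2)) == {"f0", "f1"}

    def test_separating_column_ranked_first(self):
        X, y = self.toy()
        assert select_k_best(X, y, 2)[0] == "f0"
        assert select_k_best(X, y, 1) == ["f0"]

    def test_constant_column_ranked_last(self):
        X, y = self.toy()
        X = np.column_stack([np.full(6, 7.0), X])
        assert select_k_best(X, y, 3)[-1] == "f0"  # the constant column

    def test_invalid_k(self):
        X, y = self.toy()
        with pytest.raises(ValueError):
            select_k_best(X, y, 0)
        with pytest.raises(ValueError):
            select_k_best(X, y, 5)
        with pytest.raises(ValueError):
            select_k_best(X, [0] * 6, 1)
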