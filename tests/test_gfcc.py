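import numpy as np
import pytest

from crydiag.gfcc import (
    FramingConfig,
    GfccConfig,
    GfccExtractor,
    build_filterbank,
    erb_center_frequencies,
    frame_signal,
    gfcc_frames,
    segment_gfcc,
)
from crydiag.io import CrySegment

from conftest import make_tone_segment

SR = 44100


def erb_rate_oracle(f):
    """Independent Glasberg-Moore ERB-rate formula (Cam)."""
    return 21.4 * np.log10(1 + 0.00437 * np.asarray(f))


def dct2_ortho_oracle(v):
    """Brute-force orthonormal DCT-II by its double-loop definition."""
    n = len(v)
    out = np.zeros(n)
    for k in range(n):
        acc = 0.0
        for i in range(n):
            acc += v[i] * np.cos(np.pi * k * (2 * i + 1) / (2 * n))
        scale = np.sqrt(1.0 / n) if k == 0 else np.sqrt(2.0 / n)
        out[k] = scale * acc
    return out


class TestFraming:
    def test_one_second_frame_count(self):
        # W = round(0.010*44100) = 441, H = round(0.007*44100) = 309
        # floor((44100 - 441)/309) + 1 = 142
        seg = make_tone_segment(duration=1.0)
        fm = frame_signal(seg)
        assert fm.frames.shape == (142, 441)
        assert fm.hop_samples == 309

    def test_exactly_one_frame(self):
        seg = CrySegment(np.ones(441), SR)
        assert frame_signal(seg).n_frames == 1

    def test_all_ones_rows_equal_taper(self):
        seg = CrySegment(np.ones(2000), SR)
        fm = frame_signal(seg)
        taper = np.hamming(441)
        for row in fm.frames:
            assert np.allclose(row, taper)

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError, match="too short"):
            frame_signal(CrySegment(np.ones(100), SR))

    @pytest.mark.parametrize("trial", range(10))
    def test_start_indices_match_enumeration(self, trial, rng):
        # brute-force enumeration oracle over random (L, sr) pairs
        local = np.random.default_rng(trial)
        sr = int(local.integers(8000, 48000))
        cfg = FramingConfig()
        w, h = cfg.frame_samples(sr), cfg.hop_samples(sr)
        length = int(local.integers(w, 6 * w))
        x = local.uniform(-1, 1, length)
        fm = frame_signal(CrySegment(x, sr), cfg)
        starts = [s for s in range(0, length - w + 1) if s % h == 0]
        assert fm.n_frames == len(starts)
        taper = np.hamming(w)
        for row, s in zip(fm.frames, starts):
            assert np.array_equal(row, x[s : s + w] * taper)


class TestErbScale:
    def test_endpoints(self):
        freqs = erb_center_frequencies(2, 50, 8000)
        assert freqs[0] == pytest.approx(50)
        assert freqs[-1] == pytest.approx(8000)

    def test_strictly_increasing(self):
        freqs = erb_center_frequencies(64, 50, 8000)
        assert np.all(np.diff(freqs) > 0)

    def test_uniform_on_erb_rate_scale(self):
        freqs = erb_center_frequencies(64, 50, 8000)
        cams = erb_rate_oracle(freqs)
        assert np.allclose(np.diff(cams), np.diff(cams)[0], atol=1e-9)

    def test_too_few_filters_raises(self):
        with pytest.raises(ValueError):
            erb_center_frequencies(1, 50, 8000)


class TestFilterbank:
    def test_peaks_at_center_frequencies(self):
        fb = build_filterbank(40, 50, 8000, 512, SR)
        bin_hz = SR / 512
        for k in range(fb.n_filters):
            peak_freq = np.argmax(fb.weights[k]) * bin_hz
            assert abs(peak_freq - fb.center_freqs[k]) <= bin_hz

    def test_weights_nonnegative_unit_peak(self):
        fb = build_filterbank(32, 50, 7000, 512, SR)
        assert np.all(fb.weights >= 0)
        assert np.allclose(fb.weights.max(axis=1), 1.0)

    def test_doubling_nfft_keeps_peaks(self):
        fb1 = build_filterbank(24, 100, 6000, 512, SR)
        fb2 = build_filterbank(24, 100, 6000, 1024, SR)
        f1 = np.argmax(fb1.weights, axis=1) * SR / 512
        f2 = np.argmax(fb2.weights, axis=1) * SR / 1024
        assert np.all(np.abs(f1 - f2) <= SR / 512)

    def test_bandwidths_increase_with_index(self):
        fb = build_filterbank(32, 50, 8000, 1024, SR)
        # -3 dB width in bins grows with the centre frequency
        widths = [(fb.weights[k] > 0.5).sum() for k in range(fb.n_filters)]
        assert widths[-1] > widths[0]

    def test_fmax_at_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            build_filterbank(32, 50, SR / 2, 512, SR)


class TestGfccFrames:
    def test_all_zero_frame_finite_and_flat(self):
        seg = CrySegment(np.zeros(2000), SR)
        ceps = gfcc_frames(frame_signal(seg))
        assert np.all(np.isfinite(ceps))
        assert np.allclose(ceps[:, 1:], 0.0, atol=1e-9)

    def test_matches_brute_force_dct(self, rng):
        seg = CrySegment(rng.uniform(-1, 1, 3000), SR)
        fm = frame_signal(seg)
        cfg = GfccConfig()
        ceps = gfcc_frames(fm, cfg)
        # recompute one frame end-to-end with the double-loop DCT oracle
        from scipy.fft import rfft

        fb = build_filterbank(cfg.n_filters, cfg.fmin, cfg.fmax, 512, SR)
        power = np.abs(rfft(fm.frames[0], n=512)) ** 2
        energies = fb.weights @ power
        floor = max(energies.max(), 1.0) * cfg.log_floor_rel
        log_e = np.log(np.maximum(energies, floor))
        assert np.allclose(ceps[0], dct2_ortho_oracle(log_e)[:13], atol=1e-9)

    def test_dct_orthonormality(self):
        from scipy.fft import dct

        mat = dct(np.eye(64), type=2, norm="ortho", axis=0)
        assert np.allclose(mat @ mat.T, np.eye(64), atol=1e-10)

    def test_white_noise_coefficient0_dominates(self, rng):
        frames = rng.standard_normal((200, 441))
        seg_frames = frame_signal(
            CrySegment(np.concatenate(frames), SR)
        )
        ceps = gfcc_frames(seg_frames)
        variances = ceps.var(axis=0)
        assert np.argmax(np.abs(ceps).mean(axis=0)) == 0
        assert np.abs(ceps[:, 0]).mean() > 3 * np.abs(ceps[:, 1:]).mean()


class TestSegmentGfcc:
    def test_vector_length_13(self, tone_segment):
        assert segment_gfcc(tone_segment).shape == (13,)

    def test_stationary_input_segment_matches_single_frame(self):
        seg = make_tone_segment(freq=441.0, duration=0.3)  # exact period / frame
        vec = segment_gfcc(seg)
        single = gfcc_frames(frame_signal(seg))[5]
        assert np.max(np.abs(vec - single)) < 0.3

    def test_gain_moves_only_coefficient0(self, tone_segment):
        base = segment_gfcc(tone_segment)
        doubled = segment_gfcc(
            CrySegment(tone_segment.samples * 2.0, tone_segment.sample_rate)
        )
        assert np.allclose(doubled[1:], base[1:], atol=1e-6)
        assert doubled[0] > base[0]

    def test_extractor_shape_and_names(self, small_corpus):
        _, segments, _ = small_corpus
        extractor = GfccExtractor().fit(segments[:4])
        mat = extractor.transform(segments[:4])
        assert mat.shape == (4, 13)
        assert list(extractor.get_feature_names_out())[:2] == ["gfcc_00", "gfcc_01"]
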