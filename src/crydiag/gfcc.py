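"""Gammatone-frequency cepstral coefficients (GFCC).

The segment is windowed into short Hamming frames (10 ms frames with
3 ms overlap, i.e. a 7 ms hop), each frame's power spectrum is pooled
through a bank of Gammatone filters whose centre frequencies are spaced
uniformly on the ERB-rate scale (the psychoacoustic map of cochlear
filtering), the filter energies are log-compressed, and an orthonormal
DCT-II decorrelates them into cepstral coefficients. The per-segment
feature vector is the frame mean of the first 13 coefficients, matching
the classifier input width downstream.

The filterbank is applied in the spectral domain: each filter is the
magnitude response of a 4th-order Gammatone filter sampled at the FFT
bin frequencies and scaled to unit peak (the nth-order Gammatone is the
standard cascade of n 1st-order sections; only its frequency-domain
weighting is needed here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft, rfftfreq
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CrySegment

__all__ = [
    "FramingConfig",
    "FrameMatrix",
    "GammatoneFilterbank",
    "GfccConfig",
    "frame_signal",
    "erb_rate",
    "erb_bandwidth",
    "erb_center_frequencies",
    "build_filterbank",
    "gfcc_frames",
    "segment_gfcc",
    "GfccExtractor",
]


@dataclass(frozen=True)
class FramingConfig:
    """Short-term analysis framing: 10 ms Hamming frames, 3 ms overlap."""

    frame_len_s: float = 0.010
    overlap_s: float = 0.003
    window: str = "hamming"

    def __post_init__(self):
        if not (0 < self.overlap_s < self.frame_len_s):
            raise ValueError("require 0 < overlap_s < frame_len_s")

    def frame_samples(self, sample_rate: int) -> int:
        return int(round(self.frame_len_s * sample_rate))

    def hop_samples(self, sample_rate: int) -> int:
        # hop = frame length minus overlap, rounded to the nearest sample
        return int(round((self.frame_len_s - self.overlap_s) * sample_rate))


@dataclass(frozen=True)
class FrameMatrix:
    """Windowed frames: rows are contiguous signal spans times the taper."""

    frames: np.ndarray
    hop_samples: int
    sample_rate: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def frame_signal(segment: CrySegment, config: FramingConfig = FramingConfig()) -> FrameMatrix:
    """Slice a segment into overlapping windowed frames.

    Frame starts are ``0, H, 2H, ...`` with hop ``H``; the number of
    frames is ``floor((L - W) / H) + 1`` for signal length ``L`` and
    frame length ``W`` in samples.
    """
    sr = segment.sample_rate
    w = config.frame_samples(sr)
    h = config.hop_samples(sr)
    x = segment.samples
    if x.size < w:
        raise ValueError(
            f"segment too short: {x.size} samples < one {w}-sample frame"
        )
    n_frames = (x.size - w) // h + 1
    taper = np.hamming(w) if config.window == "hamming" else np.ones(w)
    starts = np.arange(n_frames) * h
    frames = np.stack([x[s : s + w] for s in starts]) * taper
    return FrameMatrix(frames=frames, hop_samples=h, sample_rate=sr)


def erb_rate(freq_hz):
    """Glasberg-Moore ERB-rate (Cam) of a frequency in Hz."""
    return 21.4 * np.log10(1.0 + 4.37e-3 * np.asarray(freq_hz, dtype=float))


def erb_rate_to_hz(erbs):
    """Inverse of :func:`erb_rate`."""
    return (10.0 ** (np.asarray(erbs, dtype=float) / 21.4) - 1.0) / 4.37e-3


def erb_bandwidth(freq_hz):
    """Equivalent rectangular bandwidth (Hz) at a centre frequency."""
    return 24.7 * (4.37e-3 * np.asarray(freq_hz, dtype=float) + 1.0)


def erb_center_frequencies(n_filters: int, fmin: float, fmax: float) -> np.ndarray:
    """Centre frequencies uniformly spaced on the ERB-rate scale.

    Endpoints are included: the first frequency is ``fmin``, the last
    ``fmax``.
    """
    if n_filters < 2:
        raise ValueError("need at least 2 filters")
    if not (0 < fmin < fmax):
        raise ValueError("require 0 < fmin < fmax")
    return erb_rate_to_hz(np.linspace(erb_rate(fmin), erb_rate(fmax), n_filters))


@dataclass(frozen=True)
class GammatoneFilterbank:
    """ERB-spaced spectral weights of 4th-order Gammatone filters."""

    center_freqs: np.ndarray
    weights: np.ndarray  # (n_filters, n_fft//2 + 1), unit peak per row
    fmin: float
    fmax: float
    n_fft: int
    sample_rate: int

    @property
    def n_filters(self) -> int:
        return self.center_freqs.size


def build_filterbank(
    n_filters: int,
    fmin: float,
    fmax: float,
    n_fft: int,
    sample_rate: int,
    order: int = 4,
) -> GammatoneFilterbank:
    """Sample Gammatone magnitude responses at the FFT bin frequencies.

    The amplitude response of an ``order``-th order Gammatone filter at
    centre ``fc`` is ``[1 + ((f - fc)/b)^2]^(-order/2)`` with the
    bandwidth parameter ``b = 1.019 * ERB(fc)``; each row is scaled to
    unit peak.
    """
    if fmax >= sample_rate / 2:
        raise ValueError("fmax must be below Nyquist")
    centers = erb_center_frequencies(n_filters, fmin, fmax)
    freqs = rfftfreq(n_fft, d=1.0 / sample_rate)
    b = 1.019 * erb_bandwidth(centers)
    resp = (1.0 + ((freqs[None, :] - centers[:, None]) / b[:, None]) ** 2) ** (-order / 2.0)
    resp /= resp.max(axis=1, keepdims=True)
    return GammatoneFilterbank(
        center_freqs=centers,
        weights=resp,
        fmin=fmin,
        fmax=fmax,
        n_fft=n_fft,
        sample_rate=sample_rate,
    )


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


@dataclass(frozen=True)
class GfccConfig:
    """Cepstral stage parameters.

    ``n_coeffs`` retained coefficients (13 by default, the classifier
    input width); ``n_filters`` Gammatone channels between ``fmin`` and
    ``fmax``; ``log_floor_rel`` floors each frame's filter energies at
    that fraction of the frame maximum before the log, so silence never
    produces ``-inf``.
    """

    n_coeffs: int = 13
    n_filters: int = 64
    fmin: float = 50.0
    fmax: float = 8000.0
    log_floor_rel: float = 1e-12

    def __post_init__(self):
        if not 1 <= self.n_coeffs <= self.n_filters:
            raise ValueError("require 1 <= n_coeffs <= n_filters")


def gfcc_frames(
    frame_matrix: FrameMatrix,
    config: GfccConfig = GfccConfig(),
    filterbank: GammatoneFilterbank | None = None,
) -> np.ndarray:
    """Per-frame GFCC matrix (n_frames x n_coeffs).

    Per frame: power spectrum (FFT size = next power of two >= frame
    length), Gammatone filterbank energies, scale-aware log floor,
    orthonormal DCT-II over the log energies, first ``n_coeffs`` kept.
    """
    w = frame_matrix.frames.shape[1]
    n_fft = _next_pow2(w)
    if filterbank is None:
        filterbank = build_filterbank(
            config.n_filters, config.fmin, config.fmax, n_fft, frame_matrix.sample_rate
        )
    elif filterbank.n_fft < w:
        raise ValueError("filterbank n_fft smaller than frame length")
    power = np.abs(rfft(frame_matrix.frames, n=filterbank.n_fft, axis=1)) ** 2
    energies = power @ filterbank.weights.T
    floor = np.maximum(energies.max(axis=1, keepdims=True), 1.0) * config.log_floor_rel
    log_e = np.log(np.maximum(energies, floor))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)
    return ceps[:, : config.n_coeffs]


def segment_gfcc(
    segment: CrySegment,
    framing: FramingConfig = FramingConfig(),
    config: GfccConfig = GfccConfig(),
    filterbank: GammatoneFilterbank | None = None,
) -> np.ndarray:
    """Segment-level GFCC vector: frame mean of the cepstral matrix."""
    return gfcc_frames(frame_signal(segment, framing), config, filterbank).mean(axis=0)


class GfccExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping cry segments to 13-element GFCC vectors.

    Stateless apart from a cached filterbank; `fit` only validates and
    records the feature names. Operates on a list of
    :class:`~crydiag.io.CrySegment`.
    """

    def __init__(self, n_coeffs=13, n_filters=64, fmin=50.0, fmax=8000.0,
                 frame_len_s=0.010, overlap_s=0.003):
        self.n_coeffs = n_coeffs
        self.n_filters = n_filters
        self.fmin = fmin
        self.fmax = fmax
        self.frame_len_s = frame_len_s
        self.overlap_s = overlap_s

    def _configs(self):
        return (
            FramingConfig(frame_len_s=self.frame_len_s, overlap_s=self.overlap_s),
            GfccConfig(n_coeffs=self.n_coeffs, n_filters=self.n_filters,
                       fmin=self.fmin, fmax=self.fmax),
        )

    def fit(self, X, y=None):
        self._configs()  # validates parameters
        self.feature_names_out_ = np.array(
            [f"gfcc_{k:02d}" for k in range(self.n_coeffs)]
        )
        self.n_features_out_ = self.n_coeffs
        return self

    def transform(self, X):
        framing, config = self._configs()
        fb_cache: dict[tuple[int, int], GammatoneFilterbank] = {}
        rows = []
        for seg in X:
            w = framing.frame_samples(seg.sample_rate)
            key = (seg.sample_rate, _next_pow2(w))
            if key not in fb_cache:
                # cap the band edge below Nyquist for low-rate audio
                fmax = min(config.fmax, 0.499 * seg.sample_rate)
                fb_cache[key] = build_filterbank(
                    config.n_filters, config.fmin, fmax, key[1], seg.sample_rate
                )
            rows.append(segment_gfcc(seg, framing, config, fb_cache[key]))
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        return np.array([f"gfcc_{k:02d}" for k in range(self.n_coeffs)])
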