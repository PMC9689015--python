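"""Harmonic ratio (HR): per-frame harmonicity and its segment statistics.

The harmonic ratio of a frame measures the proportion of the frame's
energy attributable to periodic (harmonic) structure, as a value in
[0, 1]. It is estimated as the maximum of the normalised
autocorrelation over the lag window corresponding to a plausible cry
fundamental (150-1000 Hz by default):

    HR = max_{tau in [sr/f0_high, sr/f0_low]}  r(tau) / sqrt(E0(tau) * Etau)

with r(tau) = sum_t x[t] x[t+tau] and the two energy terms taken over
the overlapping spans, so a perfectly periodic frame scores 1 and white
noise scores near 0. Negative maxima are clipped to 0.

HR frames are longer than the cepstral frames (40 ms vs 10 ms) so at
least one period of the lowest search fundamental fits in the window.
A segment is summarised by four statistics of its HR series — mean,
median, interquartile range and standard deviation — giving the
4-element feature vector used downstream. The IQR uses linear
interpolation between order statistics and the standard deviation the
n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CrySegment

__all__ = [
    "HrConfig",
    "HarmonicRatioSeries",
    "harmonic_ratio_frame",
    "harmonic_ratio_series",
    "summarize",
    "segment_hr_stats",
    "HR_STAT_NAMES",
    "HarmonicRatioExtractor",
]

HR_STAT_NAMES = ("hr_mean", "hr_median", "hr_iqr", "hr_std")


@dataclass(frozen=True)
class HrConfig:
    frame_len_s: float = 0.040
    hop_s: float = 0.010
    f0_search: tuple = (150.0, 1000.0)

    def __post_init__(self):
        if self.frame_len_s <= 0 or self.hop_s <= 0:
            raise ValueError("frame_len_s and hop_s must be positive")
        low, high = self.f0_search
        if not (0 < low < high):
            raise ValueError("f0_search must be an increasing positive interval")
        if 1.0 / low > self.frame_len_s:
            raise ValueError(
                "frame_len_s must cover at least one period of f0_search low bound"
            )


@dataclass(frozen=True)
class HarmonicRatioSeries:
    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self):
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times lengths differ")


def _lag_window(n_frame: int, sample_rate: int, f0_search) -> tuple[int, int]:
    lag_min = max(1, int(np.ceil(sample_rate / f0_search[1])))
    lag_max = int(np.floor(sample_rate / f0_search[0]))
    if n_frame <= lag_max or lag_max < lag_min:
        raise ValueError(
            "frame too short: must cover one period of the lowest search F0"
        )
    return lag_min, lag_max


def harmonic_ratio_frame(frame, sample_rate: int, f0_search=(150.0, 1000.0)) -> float:
    """Harmonic ratio of a single frame, in [0, 1]; 0 for silent frames."""
    x = np.asarray(frame, dtype=np.float64)
    lag_min, lag_max = _lag_window(x.size, sample_rate, f0_search)
    total = float(np.dot(x, x))
    if total <= 0.0:
        return 0.0
    # raw autocorrelation for all lags at once (zero-padded FFT)
    n_fft = 1 << int(2 * x.size - 1).bit_length()
    spec = rfft(x, n=n_fft)
    ac = irfft(spec * np.conj(spec), n=n_fft)[: x.size]
    lags = np.arange(lag_min, lag_max + 1)
    # energies of the leading span x[0:n-tau] and trailing span x[tau:n]
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    e_head = csum[x.size - lags] - csum[0]
    e_tail = csum[x.size] - csum[lags]
    denom = np.sqrt(e_head * e_tail)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, ac[lags] / denom, 0.0)
    return float(np.clip(r.max(), 0.0, 1.0))


def harmonic_ratio_series(segment: CrySegment, config: HrConfig = HrConfig()) -> HarmonicRatioSeries:
    """HR for every frame of a segment."""
    sr = segment.sample_rate
    w = int(round(config.frame_len_s * sr))
    h = int(round(config.hop_s * sr))
    x = segment.samples
    if x.size < w:
        raise ValueError(f"segment too short: {x.size} samples < one {w}-sample HR frame")
    starts = np.arange(0, x.size - w + 1, h)
    values = np.array(
        [harmonic_ratio_frame(x[s : s + w], sr, config.f0_search) for s in starts]
    )
    return HarmonicRatioSeries(values=values, frame_times=starts / sr)


def summarize(values) -> np.ndarray:
    """(mean, median, IQR, std) of an HR series.

    IQR interpolates linearly between order statistics; std uses the
    n-1 denominator (0 for a single value).
    """
    values = np.asarray(values, dtype=np.float64)
    q75, q25 = np.percentile(values, [75, 25])
    std = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return np.array([float(np.mean(values)), float(np.median(values)), q75 - q25, std])


def segment_hr_stats(segment: CrySegment, config: HrConfig = HrConfig()) -> np.ndarray:
    """(mean, median, IQR, std) of the segment's HR series."""
    return summarize(harmonic_ratio_series(segment, config).values)


class HarmonicRatioExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping cry segments to 4-element HR statistic vectors."""

    def __init__(self, frame_len_s=0.040, hop_s=0.010, f0_low=150.0, f0_high=1000.0):
        self.frame_len_s = frame_len_s
        self.hop_s = hop_s
        self.f0_low = f0_low
        self.f0_high = f0_high

    def _config(self):
        return HrConfig(
            frame_len_s=self.frame_len_s, hop_s=self.hop_s,
            f0_search=(self.f0_low, self.f0_high),
        )

    def fit(self, X, y=None):
        self._config()
        self.feature_names_out_ = np.array(HR_STAT_NAMES)
        self.n_features_out_ = len(HR_STAT_NAMES)
        return self

    def transform(self, X):
        config = self._config()
        return np.asarray([segment_hr_stats(seg, config) for seg in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(HR_STAT_NAMES)
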