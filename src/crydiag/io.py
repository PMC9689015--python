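"""WAV and segment-label I/O.

Recordings are mono or stereo RIFF PCM WAV files (the target corpus was
recorded at 16-bit / 44.1 kHz). Each recording comes with a plain-text
transcription file marking labelled intervals; expiratory cry intervals
(tag ``EXP``) are the unit sample of the downstream analysis.

Label-file dialect: one interval per line, whitespace-separated
``start end tag`` with times in seconds. Column order is configurable for
transcription tools that emit ``tag start end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "SegmentLabel",
    "CrySegment",
    "read_wav",
    "write_wav",
    "parse_label_file",
    "extract_segments",
    "trim_silence",
]

#: PCM integer full-scale values keyed by numpy dtype kind/width.
_PCM_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal with samples in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("waveform must be a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class SegmentLabel:
    """A labelled time interval inside a recording."""

    start_s: float
    end_s: float
    tag: str

    def __post_init__(self):
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValueError(
                f"end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )
        if not self.tag:
            raise ValueError("tag must be non-empty")


@dataclass(frozen=True)
class CrySegment:
    """One expiratory cry segment, the unit sample of the pipeline."""

    samples: np.ndarray
    sample_rate: int
    class_label: str = "unknown"
    recording_id: str = ""
    subject_id: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("segment must be a non-empty 1-D sample array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


def read_wav(path) -> Waveform:
    """Read a PCM (or float) WAV file as a mono [-1, 1] waveform.

    Multi-channel audio is collapsed to mono by the channel mean; the
    recorder used for the target corpus is 2-channel and no channel
    policy is implied by the data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sample_rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"{path}: zero-length audio")
    if data.ndim == 2:
        data = data.mean(axis=1, dtype=np.float64)
    data = np.asarray(data)
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit PCM is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    samples = np.clip(samples, -1.0, 1.0)
    return Waveform(samples=samples, sample_rate=int(sample_rate), source_id=path.stem)


def write_wav(path, waveform: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    pcm = np.clip(np.round(waveform.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), waveform.sample_rate, pcm)


def parse_label_file(path, columns=("start", "end", "tag")) -> list[SegmentLabel]:
    """Parse a transcription label file into labels sorted by start time.

    Parameters
    ----------
    path : path-like
        Text file with one whitespace-separated interval per line.
    columns : tuple of str
        Order of the three fields on each line; any permutation of
        ``("start", "end", "tag")``.
    """
    if sorted(columns) != ["end", "start", "tag"]:
        raise ValueError(f"columns must be a permutation of start/end/tag, got {columns}")
    idx = {name: i for i, name in enumerate(columns)}
    labels = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                start = float(parts[idx["start"]])
                end = float(parts[idx["end"]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric interval bounds") from exc
            try:
                labels.append(SegmentLabel(start, end, parts[idx["tag"]]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    labels.sort(key=lambda lab: lab.start_s)
    return labels


def extract_segments(
    waveform: Waveform,
    labels,
    keep_tag: str = "EXP",
    class_label: str = "unknown",
    subject_id: str = "",
) -> list[CrySegment]:
    """Cut the intervals whose tag equals ``keep_tag`` out of a waveform.

    Sample ranges are half-open ``[round(start*sr), round(end*sr))`` so
    adjacent intervals never share a sample. A label ending past the
    waveform is an error; an absent tag yields an empty list.
    """
    sr = waveform.sample_rate
    n = waveform.samples.size
    segments = []
    for lab in labels:
        if lab.tag != keep_tag:
            continue
        lo = int(round(lab.start_s * sr))
        hi = int(round(lab.end_s * sr))
        if hi > n:
            raise ValueError(
                f"label {lab.start_s:.3f}-{lab.end_s:.3f}s exceeds waveform "
                f"duration {n / sr:.3f}s"
            )
        if hi <= lo:
            raise ValueError(f"label {lab.start_s}-{lab.end_s}s rounds to an empty slice")
        segments.append(
            CrySegment(
                samples=waveform.samples[lo:hi].copy(),
                sample_rate=sr,
                class_label=class_label,
                recording_id=waveform.source_id,
                subject_id=subject_id,
                meta={"start_s": lab.start_s, "end_s": lab.end_s},
            )
        )
    return segments


def trim_silence(
    segment: CrySegment, frame_ms: float = 10.0, threshold_db: float = -40.0
) -> CrySegment:
    """Strip leading/trailing low-energy frames from a segment.

    Frames whose RMS falls below ``threshold_db`` relative to the peak
    frame RMS of the segment are treated as silence; only the leading
    and trailing runs are removed, interior frames are untouched.
    """
    if frame_ms <= 0:
        raise ValueError("frame_ms must be positive")
    x = segment.samples
    flen = max(1, int(round(frame_ms * 1e-3 * segment.sample_rate)))
    n_frames = int(np.ceil(x.size / flen))
    rms = np.array(
        [np.sqrt(np.mean(x[i * flen : (i + 1) * flen] ** 2)) for i in range(n_frames)]
    )
    peak = rms.max()
    if peak <= 0:
        raise ValueError("segment empty after trim: all-silent input")
    keep = rms >= peak * 10.0 ** (threshold_db / 20.0)
    active = np.flatnonzero(keep)
    if active.size == 0:
        raise ValueError("segment empty after trim")
    lo = active[0] * flen
    hi = min(x.size, (active[-1] + 1) * flen)
    return replace(segment, samples=x[lo:hi].copy())
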