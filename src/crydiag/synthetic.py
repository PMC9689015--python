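"""Synthetic expiratory cry generator (source-filter model).

The clinical corpus behind the original study is private, so the pipeline
is exercised on synthetic expiratory segments built from the classic
source-filter view of phonation: a harmonic series at the cry fundamental
(the glottal source) is shaped by second-order resonators (formants, the
vocal-tract filter) and mixed with white noise at a controlled
harmonic-to-noise ratio (HNR). The two knobs map one-to-one onto the two
feature families under test: HNR drives the harmonic-ratio statistics,
the formant layout drives the Gammatone cepstrum.

All randomness flows through one :class:`numpy.random.Generator`; no
global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import CrySegment

__all__ = [
    "CryClassSpec",
    "CorpusSpec",
    "default_corpus_spec",
    "generate_segment",
    "generate_corpus",
]


@dataclass(frozen=True)
class CryClassSpec:
    """Acoustic parameters for one pathology class.

    Parameters
    ----------
    f0_range : (float, float)
        Uniform sampling band for the cry fundamental, Hz.
    n_harmonics : int
        Harmonics synthesised (those above Nyquist are dropped).
    formant_centers, formant_bandwidths : sequence of float
        Centre frequency and -3 dB bandwidth of each vocal-tract
        resonance, Hz.
    harmonic_to_noise_db : float or (float, float)
        Power ratio of the harmonic component to the noise component,
        dB; an interval is sampled uniformly per segment (newborn
        phonation quality varies strongly from cry to cry). ``+inf``
        disables noise, ``-inf`` disables the harmonics.
    duration_range : (float, float)
        Uniform sampling band for segment duration, seconds.
    amplitude_jitter : float
        Fractional multiplicative jitter applied per harmonic partial.
    formant_jitter : float
        Fractional multiplicative jitter applied per segment to every
        formant centre (vocal-tract variability between newborns).
    noise_through_formants : bool
        Shape the noise with the same vocal-tract filter as the
        harmonic source (aspiration noise originates at the glottis and
        traverses the same tract). This keeps the spectral envelope —
        what the cepstral features measure — nearly independent of the
        harmonic-to-noise ratio, which only the harmonic-ratio features
        then resolve. Set False for plain white background noise.
    """

    f0_range: tuple = (400.0, 600.0)
    n_harmonics: int = 30
    formant_centers: tuple = (1100.0, 3300.0)
    formant_bandwidths: tuple = (200.0, 400.0)
    harmonic_to_noise_db: float | tuple = 10.0
    duration_range: tuple = (0.55, 0.9)
    amplitude_jitter: float = 0.3
    formant_jitter: float = 0.0
    noise_through_formants: bool = True

    def __post_init__(self):
        if not (0 < self.f0_range[0] <= self.f0_range[1]):
            raise ValueError("f0_range must be a positive interval")
        if not (0 < self.duration_range[0] <= self.duration_range[1]):
            raise ValueError("duration_range must be a positive interval")
        if len(self.formant_centers) != len(self.formant_bandwidths):
            raise ValueError("formant_centers and formant_bandwidths lengths differ")
        if np.any(np.isnan(self.hnr_bounds)):
            raise ValueError("harmonic_to_noise_db must not be NaN")
        if not 0 <= self.formant_jitter < 1:
            raise ValueError("formant_jitter must be in [0, 1)")

    @property
    def hnr_bounds(self) -> tuple:
        hnr = self.harmonic_to_noise_db
        return tuple(hnr) if np.ndim(hnr) else (float(hnr), float(hnr))


@dataclass(frozen=True)
class CorpusSpec:
    """A balanced two-class synthetic corpus."""

    class_a: CryClassSpec
    class_b: CryClassSpec
    n_per_class: int = 200
    sample_rate: int = 44100
    seed: int = 0
    label_a: str = "septic"
    label_b: str = "rds"
    segments_per_subject: int = 5

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.segments_per_subject < 1:
            raise ValueError("segments_per_subject must be >= 1")


def default_corpus_spec(seed: int = 0, n_per_class: int = 200) -> CorpusSpec:
    """Study conditions for the default synthetic corpus.

    The class contrast is deliberately split across the two feature
    modalities: septic segments carry a higher harmonic-to-noise ratio
    (cleaner phonation, higher harmonic ratio) while the two classes
    differ moderately in formant placement (shifting the spectral
    envelope the Gammatone cepstrum measures). Both classes share the
    same F0 band so pitch itself carries no label signal. Durations
    follow the 0.71 s / 0.74 s average expiratory segment lengths of
    the corpus the pipeline targets.
    """
    septic = CryClassSpec(
        f0_range=(400.0, 600.0),
        n_harmonics=30,
        formant_centers=(1100.0, 3200.0),
        formant_bandwidths=(250.0, 450.0),
        harmonic_to_noise_db=(3.0, 14.0),
        duration_range=(0.5, 0.92),
        amplitude_jitter=0.35,
        formant_jitter=0.09,
    )
    rds = CryClassSpec(
        f0_range=(400.0, 600.0),
        n_harmonics=30,
        formant_centers=(1240.0, 3390.0),
        formant_bandwidths=(250.0, 450.0),
        harmonic_to_noise_db=(-7.0, 5.0),
        duration_range=(0.53, 0.95),
        amplitude_jitter=0.35,
        formant_jitter=0.09,
    )
    return CorpusSpec(class_a=septic, class_b=rds, n_per_class=n_per_class, seed=seed)


def _formant_sos(centers, bandwidths, sample_rate):
    """Cascade of 2nd-order resonators as second-order sections."""
    sections = []
    for fc, bw in zip(centers, bandwidths):
        r = np.exp(-np.pi * bw / sample_rate)
        theta = 2.0 * np.pi * fc / sample_rate
        # poles at r * exp(+-j theta); unit gain at the pole angle
        b0 = (1 - r) * np.sqrt(1 - 2 * r * np.cos(2 * theta) + r * r)
        sections.append([b0, 0.0, 0.0, 1.0, -2.0 * r * np.cos(theta), r * r])
    return np.asarray(sections)


def generate_segment(
    spec: CryClassSpec,
    sample_rate: int,
    rng: np.random.Generator,
    class_label: str = "unknown",
    recording_id: str = "",
    subject_id: str = "",
) -> CrySegment:
    """Synthesise one expiratory cry segment.

    The harmonic component is a formant-filtered sum of partials at
    multiples of a randomly drawn F0 with 1/k amplitude roll-off and
    per-partial amplitude jitter. White Gaussian noise is then scaled
    so the component powers realise ``spec.harmonic_to_noise_db``
    exactly, and the mixture is peak-normalised to 0.9.
    """
    nyquist = sample_rate / 2.0
    if max(spec.formant_centers, default=0.0) >= nyquist:
        raise ValueError("formant center at or above Nyquist")
    if spec.f0_range[1] >= nyquist:
        raise ValueError("f0_range reaches Nyquist")

    f0 = rng.uniform(*spec.f0_range)
    duration = rng.uniform(*spec.duration_range)
    hnr_lo, hnr_hi = spec.hnr_bounds
    hnr_db = hnr_lo if hnr_lo == hnr_hi else rng.uniform(hnr_lo, hnr_hi)
    n = max(1, int(round(duration * sample_rate)))
    t = np.arange(n) / sample_rate

    make_harm = hnr_db != -np.inf
    make_noise = hnr_db != np.inf

    sos = None
    if len(spec.formant_centers) > 0:
        centers = np.asarray(spec.formant_centers, dtype=float)
        if spec.formant_jitter > 0:
            centers = centers * (
                1.0 + spec.formant_jitter * rng.uniform(-1, 1, centers.size)
            )
            centers = np.minimum(centers, 0.98 * nyquist)
        sos = _formant_sos(centers, spec.formant_bandwidths, sample_rate)

    harm = np.zeros(n)
    if make_harm:
        for k in range(1, spec.n_harmonics + 1):
            fk = k * f0
            if fk >= nyquist:
                break
            amp = (1.0 / k) * (1.0 + spec.amplitude_jitter * rng.uniform(-1, 1))
            harm += amp * np.sin(2.0 * np.pi * fk * t + rng.uniform(0, 2 * np.pi))
        if sos is not None:
            harm = sps.sosfilt(sos, harm)

    noise = rng.standard_normal(n) if make_noise else np.zeros(n)
    if make_noise and spec.noise_through_formants and sos is not None:
        noise = sps.sosfilt(sos, noise)

    p_harm = float(np.mean(harm**2))
    p_noise = float(np.mean(noise**2))
    if make_harm and make_noise and p_harm > 0 and p_noise > 0:
        target_p_noise = p_harm / 10.0 ** (hnr_db / 10.0)
        noise *= np.sqrt(target_p_noise / p_noise)
        p_noise = target_p_noise
    achieved = (
        10.0 * np.log10(p_harm / p_noise) if p_harm > 0 and p_noise > 0
        else (np.inf if p_noise == 0 else -np.inf)
    )
    x = harm + noise
    peak = np.abs(x).max()
    if peak > 0:
        x *= 0.9 / peak
    return CrySegment(
        samples=x,
        sample_rate=sample_rate,
        class_label=class_label,
        recording_id=recording_id,
        subject_id=subject_id,
        meta={
            "f0_hz": f0,
            "duration_s": n / sample_rate,
            "hnr_db": hnr_db,
            "achieved_hnr_db": float(achieved),
        },
    )


def generate_corpus(spec: CorpusSpec):
    """Generate a balanced corpus and its manifest.

    Returns
    -------
    segments : list of CrySegment
        ``2 * n_per_class`` segments, exactly balanced.
    manifest : pandas.DataFrame
        One row per segment: ids, label, per-segment seed and draw
        parameters. Together with the class specs it fully determines
        regeneration (each segment is drawn from its own child seed).
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * spec.n_per_class)
    segments, rows = [], []
    per_subj = spec.segments_per_subject
    for i, (label, cls) in enumerate(
        [(spec.label_a, spec.class_a), (spec.label_b, spec.class_b)]
    ):
        for j in range(spec.n_per_class):
            idx = i * spec.n_per_class + j
            subject = f"{label}_subj{j // per_subj:03d}"
            rec = f"{label}_rec{j:04d}"
            seg = generate_segment(
                cls,
                spec.sample_rate,
                np.random.default_rng(children[idx]),
                class_label=label,
                recording_id=rec,
                subject_id=subject,
            )
            segments.append(seg)
            rows.append(
                {
                    "index": idx,
                    "recording_id": rec,
                    "subject_id": subject,
                    "class_label": label,
                    "seed_entropy": spec.seed,
                    "child_index": idx,
                    **seg.meta,
                }
            )
    return segments, pd.DataFrame(rows)


def regenerate_from_manifest(spec: CorpusSpec, manifest: pd.DataFrame):
    """Rebuild the exact segments a manifest describes (determinism check)."""
    if int(manifest["seed_entropy"].iloc[0]) != spec.seed:
        raise ValueError("manifest was produced under a different corpus seed")
    segments, _ = generate_corpus(spec)
    return [segments[int(i)] for i in manifest["child_index"]]


def class_spec_summary(spec: CryClassSpec) -> dict:
    """Flat dict view of a class spec, for manifests and logs."""
    return asdict(spec)
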