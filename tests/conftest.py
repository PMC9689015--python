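import numpy as np
import pytest

from crydiag.io import CrySegment
from crydiag.synthetic import CorpusSpec, CryClassSpec, generate_corpus

SR = 44100


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tone_segment(freq=440.0, duration=0.5, sample_rate=SR, label="septic"):
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    return CrySegment(
        samples=0.8 * np.sin(2 * np.pi * freq * t),
        sample_rate=sample_rate,
        class_label=label,
    )


@pytest.fixture
def tone_segment():
    return make_tone_segment()


@pytest.fixture
def noise_segment(rng):
    return CrySegment(
        samples=0.5 * rng.standard_normal(SR // 2), sample_rate=SR, class_label="rds"
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A quick, clearly separated corpus for classifier unit tests."""
    septic = CryClassSpec(
        harmonic_to_noise_db=15.0,
        formant_centers=(1000.0, 3000.0),
        duration_range=(0.25, 0.35),
    )
    rds = CryClassSpec(
        harmonic_to_noise_db=-5.0,
        formant_centers=(1600.0, 4200.0),
        duration_range=(0.25, 0.35),
    )
    spec = CorpusSpec(class_a=septic, class_b=rds, n_per_class=25,
                      sample_rate=16000, seed=7)
    segments, manifest = generate_corpus(spec)
    return spec, segments, manifest
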