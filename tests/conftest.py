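import numpy as np
import pytest

from eegtext.preprocessing import DEFAULT_MONTAGE, EEGRecording
from eegtext.synthetic import beta_vs_normal_spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_recording(n_channels=21, duration_s=300.0, rate=250.0, seed=0,
                   channel_names=None, **meta):
    """Plain Gaussian-noise recording for preprocessing-level tests."""
    gen = np.random.default_rng(seed)
    n_samples = int(duration_s * rate)
    names = channel_names or DEFAULT_MONTAGE[:n_channels]
    signal = gen.normal(0.0, 50.0, size=(len(names), n_samples)).astype(np.float32)
    return EEGRecording(signal=signal, rate=rate, channel_names=names,
                        subject_meta=meta or {"age": 40, "gender": "M",
                                              "pathological": False})


@pytest.fixture()
def noise_recording():
    return make_recording()


@pytest.fixture(scope="session")
def small_corpus():
    """Tiny preprocessed 2-class corpus shared across the slower unit tests."""
    from eegtext.pipeline import prepare_corpus
    spec = beta_vs_normal_spec(n_recordings=16, seed=99)
    return spec, prepare_corpus(spec)
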