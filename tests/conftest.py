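import numpy as np
import pytest

from eegmic import (SyntheticSpec, simulate_label_sequence, synthesize_eeg,
                    PrototypeSet)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def orthogonal_prototypes():
    """Four orthonormal zero-mean maps on 19 channels."""
    gen = np.random.default_rng(7)
    raw = gen.standard_normal((19, 4))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    maps = (q[:, :4] / np.linalg.norm(q[:, :4], axis=0)).T
    return PrototypeSet(maps=maps)


@pytest.fixture(scope="session")
def planted_recording():
    """A 60 s default-condition synthetic recording with its ground truth."""
    spec = SyntheticSpec(seed=11)
    truth = simulate_label_sequence(spec, 60.0)
    rec = synthesize_eeg(truth, spec)
    return spec, truth, rec
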