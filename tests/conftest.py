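import numpy as np
import pytest

from ecg_mdfx import synth
from ecg_mdfx.core import CLASSES


@pytest.fixture(scope="session")
def templates():
    return synth.default_templates()


@pytest.fixture(scope="session")
def clean_beats():
    """Small noiseless beat set shared across tests (20 per class)."""
    return synth.generate_beats(20, seed=3)


@pytest.fixture(scope="session")
def noisy_beats(clean_beats):
    spec = synth.noise_spec_for_snr(clean_beats, 15.0, seed=11)
    return synth.add_noise(clean_beats, spec)


@pytest.fixture(scope="session")
def multibeat_signal():
    """~3000-sample concatenated clean beat train + its noisy version."""
    beats = synth.generate_beats(12, seed=5)
    clean = np.concatenate([beats.data[i] for i in range(12)])
    holder = synth.generate_beats(1, seed=5)
    from ecg_mdfx.core import BeatMatrix
    sig = BeatMatrix(clean[None, :], np.asarray(["N"], dtype=object))
    spec = synth.noise_spec_for_snr(sig, 10.0, seed=6)
    noisy = synth.add_noise(sig, spec).data[0]
    return clean, noisy


def class_means(beats):
    return {c: beats.data[beats.labels == c].mean(axis=0) for c in CLASSES}
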