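import numpy as np
import pytest

from gkmprior import (
    GkmFeaturizer,
    ModelConfig,
    TrainingSet,
    default_motif,
    generate_genome,
    generate_peaks,
    train_gkm_svm,
)
from gkmprior import model as md


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(2, 30_000, 0.45, seed=11)


@pytest.fixture(scope="session")
def motif():
    return default_motif()


@pytest.fixture(scope="session")
def small_config():
    # desk-scale word length keeps unit tests fast; the kernel code path is
    # identical to the l=11/k=7 defaults
    return ModelConfig(l=9, k=6, d=3)


@pytest.fixture(scope="session")
def small_training_set(small_genome, motif):
    peaks, truth, genome = generate_peaks(
        small_genome, motif, n_peaks=120, peak_length=40, seed=5, gain=2.0, noise_sd=0.5
    )
    ts = md.build_training_set(genome, peaks, n_top=120, seed=5)
    return ts


@pytest.fixture(scope="session")
def small_model(small_training_set, small_config):
    return train_gkm_svm(small_training_set, small_config, seed=5)
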