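"""Shared fixtures: a scaled synthetic world and a trained classifier.

Training-dependent fixtures use 30-s segments at 40 Hz (1201 samples) and a
reduced network so the whole suite runs on one CPU in minutes; the package
default geometry (240 Hz, 7201 samples) is exercised by the non-training
tests.
"""

import numpy as np
import pytest

from ppgxai import ArtifactSpec, TrainConfig, make_labeled_dataset, train

EASY_SPEC = ArtifactSpec(kind="gaussian_noise", duration_range_s=(2.0, 8.0),
                         amplitude=4.0, count=2)

#: scaled training recipe for the easy fixture (package defaults keep the
#: reference protocol values: lr 1e-4, 50 epochs, kernel 80)
EASY_CONFIG = TrainConfig(
    depth=2,
    kernel_size=24,
    channels=8,
    learning_rate=3e-3,
    epochs=15,
    batch_size=16,
    seed=5,
)


@pytest.fixture(scope="session")
def easy_train_set():
    return make_labeled_dataset(40, 40, EASY_SPEC, seed=11, fs=40.0)


@pytest.fixture(scope="session")
def easy_test_set():
    return make_labeled_dataset(20, 20, EASY_SPEC, seed=99, fs=40.0)


@pytest.fixture(scope="session")
def trained_clf(easy_train_set):
    clf, _ = train(easy_train_set, None, EASY_CONFIG)
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
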