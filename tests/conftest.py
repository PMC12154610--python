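"""Shared fixtures.

The expensive artifacts (the desk-scale selection dataset and the network
trained on it) are built once per session and shared across the training
and representation tests.
"""

from __future__ import annotations

import pytest

from gainlisten.periphery import FilterBank, make_filterbank
from gainlisten.training import (
    ToyDataset,
    make_cue_swap_trials,
    make_selection_trials,
    make_toy_dataset,
    train_toy_model,
)

TOY_TRAIN_SEED = 1


@pytest.fixture(scope="session")
def toy_filterbank() -> FilterBank:
    return make_filterbank(16, 50.0, 1800.0, 4000.0)


@pytest.fixture(scope="session")
def toy_dataset() -> ToyDataset:
    """The desk-scale selection task: 8 words, 2 talkers, diotic, 0 dB SNR."""
    return make_toy_dataset(n_scenes=2000, seed=TOY_TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_toy_net(toy_dataset):
    net, result = train_toy_model(toy_dataset, seed=TOY_TRAIN_SEED, max_epochs=12)
    return net, result


@pytest.fixture(scope="session")
def cue_swap_trials():
    return make_cue_swap_trials(200, seed=77)


@pytest.fixture(scope="session")
def selection_trials():
    return make_selection_trials(100, seed=88)
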