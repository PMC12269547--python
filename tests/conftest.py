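"""Shared fixtures.

The trained-model fixtures are intentionally session-scoped: one
scaled-down training run feeds the parameter-recovery, behavioural and
changepoint tests.  Problem sizes (2 000 trajectories of 20-50 frames,
8 / 6 epochs) are the package's desk-scale defaults for CPU runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from diffpoint.nn import TrainConfig, train
from diffpoint.simulate import build_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed dataset for I/O, metrics and pipeline tests."""
    return build_dataset(total=60, seed=11, recipe=[
        ("SSM", {"T_range": (20, 40)}),
        ("MSM", {"T_range": (20, 40)}),
        ("QTM", {"T_range": (20, 40)}),
        ("TCM", {"T_range": (20, 40)}),
        ("DIM", {"T_range": (20, 40)}),
    ])


@pytest.fixture(scope="session")
def training_dataset():
    """Desk-scale training corpus: SSM + MSM, 20-100 frame trajectories."""
    return build_dataset(total=2000, seed=42, recipe=[
        ("SSM", {"T_range": (20, 100)}),
        ("MSM", {"T_range": (20, 100)}),
    ])


@pytest.fixture(scope="session")
def trained_alpha(training_dataset):
    """Scaled-down anomalous-exponent model (8 epochs)."""
    return train(training_dataset, "alpha", TrainConfig(max_epochs=8, seed=0))


@pytest.fixture(scope="session")
def trained_K(training_dataset):
    """Scaled-down diffusion-coefficient model (6 epochs)."""
    return train(training_dataset, "K", TrainConfig(max_epochs=6, seed=1))
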