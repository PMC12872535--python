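"""Shared fixtures.

The heavyweight session fixtures (trained models on the 200/50/50 phantom
protocol) live here so the end-to-end tests share a single training run per
configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from dualscope.model import ArchConfig
from dualscope.phantoms import PhantomSpec, generate_dataset
from dualscope.workflow import RunConfig, train


ACCEPTANCE_SPEC = PhantomSpec(seed=11)  # 64x64, 3 classes, adjacent pair


def acceptance_arch(seed: int = 7, **overrides) -> ArchConfig:
    return ArchConfig.desk_scale(seed=seed, **overrides)


def acceptance_run(**overrides) -> RunConfig:
    base = dict(epochs=16, batch_size=8, lr=3e-3, eval_every=2,
                data_seed=11, model_seed=7, train_seed=7)
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def phantom_splits():
    """200 train / 50 val / 50 test phantoms, fixed seed."""
    data = generate_dataset(ACCEPTANCE_SPEC, 300)
    return data[:200], data[200:250], data[250:300]


@pytest.fixture(scope="session")
def trained_full(phantom_splits):
    """The full model trained once on the standard protocol."""
    tr, va, _ = phantom_splits
    return train(acceptance_arch(), acceptance_run(), tr, va)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
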