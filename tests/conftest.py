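"""Shared fixtures.

The expensive end-to-end study (scaled-down training of the full model and
its three ablation variants on synthetic vertebra columns) is session-scoped
so the acceptance tests share one set of trained models.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from spinediff import SynthConfig, make_dataset
from spinediff.study import run_scaled_study

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_pairs():
    """A handful of small synthetic pairs for fast network tests."""
    cfg = SynthConfig(height=48, width=32, n_vertebrae=3)
    return make_dataset(6, (0.5, 0.25, 0.25), cfg, seed=5)


@pytest.fixture(scope="session")
def study():
    """Scaled-down end-to-end study shared by the end-to-end checks."""
    return run_scaled_study(seed=1)
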