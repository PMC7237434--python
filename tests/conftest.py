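"""Shared fixtures: compact synthetic trials and canonical geometry.

The compact scenario uses a coarser ring discretization than the default so
the whole suite stays fast; generator-closure comparisons are always made
against the same discretization the generator tuned itself with, so closure
is discretization-consistent.
"""

from __future__ import annotations

import numpy as np
import pytest

from hyolingual.pipeline import analyze_trial
from hyolingual.synthetic import SwallowScenario, generate_scenario


def compact_scenario(seed: int, **overrides) -> SwallowScenario:
    kwargs = dict(seed=seed, ring_samples=120, interior_spacing_factor=3.0)
    kwargs.update(overrides)
    return SwallowScenario(**kwargs)


@pytest.fixture(scope="session")
def noiseless_ds():
    return generate_scenario(compact_scenario(seed=7, marker_noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_ds):
    return analyze_trial(noiseless_ds)


@pytest.fixture(scope="session")
def noisy_ds():
    return generate_scenario(compact_scenario(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
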