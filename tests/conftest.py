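"""Shared fixtures: small phantom geometries and synthetic feature tables.

All fixtures are generated programmatically; nothing is loaded from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from esotox.phantom import OutcomeModel, PhantomConfig, generate_phantom
from esotox.volume import VolumeGrid


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Small tube geometry for fast unit tests (not the study conditions)."""
    return PhantomConfig.small(seed=5)


@pytest.fixture(scope="session")
def small_case(small_config):
    from esotox.phantom import _case_seed
    return generate_phantom(small_config, _case_seed(small_config.seed, 0))


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    """The study-condition geometry: 37 cc tube on a 1 mm grid."""
    return PhantomConfig(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_table(rng) -> tuple[pd.DataFrame, np.ndarray]:
    """161 patients x 40 pure-noise features with ~31.7% event labels."""
    X = pd.DataFrame(
        rng.standard_normal((161, 40)),
        columns=[f"noise_{i:02d}" for i in range(40)],
    )
    y = (rng.random(161) < 0.317).astype(int)
    return X, y


def make_ramp_volume(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0),
                     coeffs=(1.0, 2.0, 3.0)) -> VolumeGrid:
    """Separable linear ramp f(x,y,z) = ax + by + cz in physical mm."""
    nx, ny, nz = shape
    sx, sy, sz = spacing
    a, b, c = coeffs
    x = np.arange(nx)[:, None, None] * sx
    y = np.arange(ny)[None, :, None] * sy
    z = np.arange(nz)[None, None, :] * sz
    return VolumeGrid(a * x + b * y + c * z, spacing)
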