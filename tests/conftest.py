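from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from spinethrust import BranchShapeParams, SmoothingParams, generate_branch_contour

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def params() -> SmoothingParams:
    """The calibrated default smoothing parameters."""
    return SmoothingParams()


@pytest.fixture
def branch_specimen():
    """One noise-free synthetic branch with ground truth."""
    return generate_branch_contour(BranchShapeParams())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_smooth_contour(rng: np.random.Generator, n: int = 600) -> np.ndarray:
    """A generic smooth open test curve (not a branch shape)."""
    x = np.linspace(0.0, 50.0, n)
    y = (
        3.0 * np.sin(2 * np.pi * x / 50)
        + 1.5 * np.cos(2 * np.pi * x / 17 + rng.uniform(0, np.pi))
        + rng.uniform(-1, 1)
    )
    return np.column_stack([x, y])
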