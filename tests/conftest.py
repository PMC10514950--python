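"""Shared fixtures: small synthetic datasets and the desk-scale study."""

from __future__ import annotations

import numpy as np
import pytest

from cytoseg.benchmark import run_tiny_study
from cytoseg.core import ImageSample
from cytoseg.synthetic import SyntheticConfig, generate_sample

STUDY_SEED = 1


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return SyntheticConfig.tiny(seed=11)


@pytest.fixture(scope="session")
def tiny_samples(tiny_config) -> list[ImageSample]:
    return [generate_sample(tiny_config, i) for i in range(8)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_study() -> dict:
    """The full desk-scale study: 4 tiny base models x 2 tasks, 3 epochs,
    200 synthetic 64x64 training samples per task. Shared session-wide
    because it dominates the suite's runtime."""
    return run_tiny_study(seed=STUDY_SEED)


def checkerboard(h: int = 16, w: int = 16) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy + xx) % 2).astype(np.uint8)
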