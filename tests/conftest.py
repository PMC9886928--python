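from dataclasses import replace

import numpy as np
import pytest

from waspdrive import HORNET, PAPER_WASP, SpeciesParams


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def hornet() -> SpeciesParams:
    return HORNET


@pytest.fixture
def paper_wasp() -> SpeciesParams:
    return PAPER_WASP


@pytest.fixture
def mini_wasp() -> SpeciesParams:
    """Small paper-wasp population for fast scenario-level tests."""
    return replace(PAPER_WASP, K=200)
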