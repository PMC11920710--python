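import numpy as np
import pytest

import tawssnet as tn
from tawssnet.surrogate import label_model


@pytest.fixture(scope="session")
def morphs():
    """Small seeded population of bifurcation morphologies."""
    return tn.sample_morphologies(tn.TABLE_RANGES, 8, seed=42)


@pytest.fixture(scope="session")
def labeled_small(morphs):
    """One labeled model at a coarse 16x16 grid (cloud, tawss field)."""
    return label_model(morphs[0], grid_rows=16, grid_cols=16)


@pytest.fixture(scope="session")
def labeled_medium(morphs):
    """One labeled model at a 32x32 grid (cloud, tawss field)."""
    return label_model(morphs[1], grid_rows=32, grid_cols=32)
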