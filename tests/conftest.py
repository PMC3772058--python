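import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def chain():
    """Three drugs forming a nested target chain {A} < {A,B} < {A,B,C}."""
    X = np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=np.int8)
    y = np.array([0.2, 0.6, 0.9])
    return X, y


@pytest.fixture
def random_instance():
    """Factory for small random binary training panels."""

    def make(seed, n_min=2, n_max=10, m_min=1, m_max=6):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(n_min, n_max + 1))
        m = int(rng.integers(m_min, m_max + 1))
        X = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        y = rng.uniform(size=n)
        return X, y, rng

    return make


@pytest.fixture
def toy_panel_frame():
    """Small labelled panel used by IO / pipeline tests."""
    X = pd.DataFrame(
        {
            "A": [1, 1, 0, 1, 0, 1],
            "B": [0, 1, 1, 1, 0, 0],
            "C": [0, 0, 0, 1, 1, 1],
            "D": [0, 1, 1, 1, 0, 1],
        },
        index=pd.Index([f"d{i}" for i in range(1, 7)], name="drug"),
        dtype=np.int8,
    )
    y = pd.Series(
        [0.1, 0.8, 0.3, 1.0, 0.0, 0.55],
        index=X.index,
        name="efficacy",
    )
    return X, y
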