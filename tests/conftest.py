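import numpy as np
import pytest
from hypothesis import settings

import ramanclean as rc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def axis():
    """Standard instrument axis: 350-1800 cm-1 at 2 cm-1 per channel."""
    return rc.SyntheticSpec().wavenumbers


@pytest.fixture
def paperlike():
    """One seeded paper-like measurement (3 frames, 4 bands, 2 spikes)."""
    return rc.paperlike_fixture(7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def brute_erode(signal, half_width):
    """Independent O(n*w) windowed minimum with clipped (edge-replicated) windows."""
    s = np.asarray(signal, dtype=float)
    out = np.empty_like(s)
    for i in range(s.size):
        lo = max(0, i - half_width)
        hi = min(s.size, i + half_width + 1)
        out[i] = s[lo:hi].min()
    return out


def brute_dilate(signal, half_width):
    s = np.asarray(signal, dtype=float)
    out = np.empty_like(s)
    for i in range(s.size):
        lo = max(0, i - half_width)
        hi = min(s.size, i + half_width + 1)
        out[i] = s[lo:hi].max()
    return out
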