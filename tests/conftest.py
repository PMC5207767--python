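import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_staircase(cps, levels, T, noise_sd=0.0, rng=None):
    """Piecewise-constant trace from change frames and segment levels."""
    x = np.empty(T)
    bounds = [0] + list(cps) + [T]
    for j in range(len(levels)):
        x[bounds[j] : bounds[j + 1]] = levels[j]
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, T)
    return x
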