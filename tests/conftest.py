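import numpy as np
import pytest

from permtdp import GroundTruth, generate_maps


def naive_true_discovery_bound(pvals, critical_values, effective_length):
    """Independent double-loop oracle for the true-discovery bound."""
    best = 0
    u_max = min(len(pvals), effective_length)
    for u in range(1, u_max + 1):
        count = sum(1 for p in pvals if p <= critical_values[u - 1])
        best = max(best, 1 - u + count)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20240624)


@pytest.fixture
def small_maps():
    """A deterministic 8x8x8, 12-subject null dataset with mild smoothing."""
    truth = GroundTruth(
        n_subjects=12, grid_shape=(8, 8, 8), smoothing_fwhm=1.5, seed=7
    )
    return generate_maps(truth)
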