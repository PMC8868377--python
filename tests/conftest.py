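import numpy as np
import pytest

from mcagent import CenterBank, normalize_rows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_state(rng):
    """A small random (features, labels, bank) instance: n=6, Y=4, C=3, d=5."""
    n, Y, C, d = 6, 4, 3, 5
    feats = normalize_rows(rng.standard_normal((n, d)))
    labels = rng.integers(0, Y, size=n)
    bank = CenterBank.random(Y, C, d, seed=7)
    return feats, labels, bank


def naive_center_similarities(feats, weights):
    """Per-element loop oracle for feature-center inner products."""
    n, d = feats.shape
    Y, C, _ = weights.shape
    out = np.zeros((n, Y, C))
    for i in range(n):
        for j in range(Y):
            for c in range(C):
                out[i, j, c] = sum(feats[i, k] * weights[j, c, k] for k in range(d))
    return out


def naive_softmax(v, gamma):
    e = np.exp((v - v.max()) / gamma)
    return e / e.sum()
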