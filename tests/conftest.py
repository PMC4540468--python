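import numpy as np
import pytest

import sheetsampler as ss


def make_random_model(rng, K=4, N=6, pi0=0.2, wta_pairs=((0, 1),),
                      exc_pairs=((2, 3),), exc_weight=0.8):
    """Small random Bernoulli model with one WTA pair and one excitatory pair."""
    pi = rng.uniform(0.25, 0.75, (K, N))
    Winh = np.zeros((K, K))
    for a, b in wta_pairs:
        if a < K and b < K:
            Winh[a, b] = Winh[b, a] = ss.STRONG_INHIBITION
    Wexc = np.zeros((K, K))
    for a, b in exc_pairs:
        if a < K and b < K and Winh[a, b] == 0:
            Wexc[a, b] = Wexc[b, a] = exc_weight
    return ss.GenerativeModel("bernoulli", pi, np.full(N, pi0), Wexc, Winh,
                              rng.normal(scale=0.5, size=K))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model(rng):
    return make_random_model(rng)
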