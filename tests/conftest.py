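import math

import numpy as np
import pytest

from afdetect import SimConfig, build_pimap, gen_paroxysmal


@pytest.fixture(scope="session")
def pimap():
    return build_pimap()


@pytest.fixture(scope="session")
def paroxysmal_stream():
    """Seeded 500 NSR / 500 AF / 500 NSR record used across tests."""
    return gen_paroxysmal(SimConfig(seed=7))


def sliding_direct_entropy(words, N=127, alphabet=None):
    """Independent vectorised oracle: H'' at every saturated window end.

    Builds per-window counts from a one-hot cumulative sum — no shared
    code with the streaming recursion.  Returns an array aligned so that
    entry j is the entropy of words[j : j+N].
    """
    words = np.asarray(words)
    if alphabet is None:
        alphabet, inv = np.unique(words, return_inverse=True)
    else:
        inv = np.searchsorted(alphabet, words)
    onehot = np.zeros((len(words) + 1, len(alphabet)), dtype=np.int64)
    onehot[np.arange(1, len(words) + 1), inv] = 1
    cum = np.cumsum(onehot, axis=0)
    counts = cum[N:] - cum[:-N]  # (n_windows, |alphabet|)
    p = counts / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, p * np.log2(np.where(counts > 0, p, 1.0)), 0.0)
    k = (counts > 0).sum(axis=1)
    return -(k / (N * math.log2(N))) * terms.sum(axis=1)
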