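import itertools

import numpy as np
import pytest

from bcpf.core import SignedNetwork, triad_count


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_unbalanced(network: SignedNetwork) -> int:
    """Independent oracle: enumerate every triad and test its sign product."""
    s = network.signs
    count = 0
    for i, j, k in itertools.combinations(range(network.n), 3):
        if s[i, j] * s[i, k] * s[j, k] == -1:
            count += 1
    return count


def brute_force_balanced(network: SignedNetwork) -> bool:
    return brute_force_unbalanced(network) == 0


def network_from_signs(n, assignments):
    """Build a complete signed network from {(i, j): sign}; default +1."""
    s = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(s, 0)
    for (i, j), sign in assignments.items():
        s[i, j] = s[j, i] = sign
    return SignedNetwork(s)


class ScriptedRNG:
    """Duck-typed RNG stub that replays preset draws, for forcing branches."""

    def __init__(self, randoms=(), integers=()):
        self._randoms = iter(randoms)
        self._integers = iter(integers)

    def random(self):
        return next(self._randoms)

    def integers(self, *args, **kwargs):
        return next(self._integers)

    def choice(self, n, size, replace):  # pragma: no cover - not used in stubs
        raise NotImplementedError
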