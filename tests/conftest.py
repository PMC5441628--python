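import numpy as np
import pytest

from sscd import ConstraintSet, Network, Partition, encode_signed
from sscd.synthetic import FIXTURE_REGIMES, generate


def random_network(rng: np.random.Generator, n: int, p: float = 0.3) -> Network:
    A = np.triu((rng.random((n, n)) < p).astype(float), k=1)
    A = A + A.T
    return Network([f"n{i}" for i in range(n)], A)


def random_signed(rng: np.random.Generator, n: int, p: float = 0.3):
    """Random topology plus disjoint random must/cannot constraint sets."""
    net = random_network(rng, n, p)
    ii, jj = np.triu_indices(n, k=1)
    u = rng.random(ii.size)
    must = frozenset(
        (int(a), int(b)) for a, b, x in zip(ii, jj, u) if x < 0.05
    )
    cannot = frozenset(
        (int(a), int(b)) for a, b, x in zip(ii, jj, u) if 0.05 <= x < 0.10
    )
    cs = ConstraintSet(must=must, cannot=cannot)
    return encode_signed(net, cs), cs


def random_partition(rng: np.random.Generator, n: int, k: int) -> Partition:
    m = rng.integers(0, k, size=n)
    m[rng.permutation(n)[:k]] = np.arange(k)  # ensure every community occupied
    return Partition(m, k)


@pytest.fixture(scope="session")
def easy_instance():
    return generate(FIXTURE_REGIMES["easy"])


@pytest.fixture(scope="session")
def ambiguous_instance():
    return generate(FIXTURE_REGIMES["ambiguous"])
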