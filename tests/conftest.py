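import itertools

import numpy as np
import pytest

from revscen.signed_perm import Arrangement, identity


@pytest.fixture(scope="session")
def ancestral():
    return identity(8, "ancestral")


@pytest.fixture(scope="session")
def x1():
    return Arrangement((1, -6, -5, 3, 4, -2, 7, 8), "X1")


@pytest.fixture(scope="session")
def x2():
    return Arrangement((1, -6, 2, -4, -3, 5, 7, 8), "X2")


@pytest.fixture(scope="session")
def x0():
    return Arrangement((1, -6, -5, 3, -7, 2, -4, 8), "X0")


@pytest.fixture(scope="session")
def bundle():
    from revscen.fixtures import load_fixture

    return load_fixture("anopheles_x")


def all_signed_arrangements(n):
    """Every signed permutation of n blocks, as Arrangement objects."""
    for perm in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            yield Arrangement(tuple(s * p for s, p in zip(signs, perm)))


def random_arrangement(rng: np.random.Generator, n: int) -> Arrangement:
    perm = rng.permutation(n) + 1
    signs = rng.choice([1, -1], size=n)
    return Arrangement(tuple(int(p * s) for p, s in zip(perm, signs)))
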