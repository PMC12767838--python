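import itertools
import random

import pytest

from grnlogic.core import DiscreteFunction
from grnlogic.fixtures import add_rule, fancm_rule


@pytest.fixture(scope="session")
def add():
    """The 5-input ADD rule over (ADD, FAN1, MUS81, PCNATLS, XPF)."""
    return add_rule()


@pytest.fixture(scope="session")
def fancm():
    return fancm_rule()


@pytest.fixture(scope="session")
def xor2():
    return DiscreteFunction(2, 2, (0, 1, 1, 0))


def random_tables(count, k, m, seed):
    """Deterministic stream of random complete tables."""
    rng = random.Random(seed)
    return [DiscreteFunction(k, m, tuple(rng.randrange(m)
                                         for _ in range(m ** k)))
            for _ in range(count)]


def all_boolean_functions(k):
    """Every Boolean rule of arity k (2**2**k tables)."""
    size = 2 ** k
    for bits in itertools.product((0, 1), repeat=size):
        yield DiscreteFunction(k, 2, bits)
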