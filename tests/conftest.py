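import numpy as np
import pytest

from protoflux import SLOW_KCN, FAST_KCN, SpeciesCounts, table1


@pytest.fixture(scope="session")
def p_default():
    """Default (Table-1) parameter preset."""
    return table1()


@pytest.fixture(scope="session")
def p_null():
    """Null model: no nucleotide catalysis of anything."""
    return table1(k_cn=0.0, k_nn=0.0)


@pytest.fixture(scope="session")
def p_slow():
    return table1(k_cn=SLOW_KCN)


@pytest.fixture(scope="session")
def p_fast():
    return table1(k_cn=FAST_KCN)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220911)


def random_state(rng, fa_range=(10.0, 5000.0)) -> SpeciesCounts:
    """A random valid cell state (fa positive, all counts non-negative)."""
    fa = rng.uniform(*fa_range)
    other = rng.uniform(0.0, 3.0, size=5) * fa
    return SpeciesCounts(fa, *other)
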