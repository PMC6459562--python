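import numpy as np
import pytest

from edgegames import (
    DegreeProfile,
    additive_tensor,
    generate_typed_graph,
    pairwise_tensor,
    volunteers_table,
)


@pytest.fixture(scope="session")
def profile32():
    return DegreeProfile((3, 2))


@pytest.fixture(scope="session")
def profile33():
    return DegreeProfile((3, 3))


@pytest.fixture(scope="session")
def k4_graph():
    """The complete graph on 4 nodes (the only 3-regular simple graph)."""
    return generate_typed_graph(4, DegreeProfile((3,)), seed=1)


@pytest.fixture(scope="session")
def small_typed_graph():
    """N=8 graph with two edge types, g=(2,1)."""
    return generate_typed_graph(8, DegreeProfile((2, 1)), seed=2)


@pytest.fixture(scope="session")
def donation_tensor_k3():
    """Single-type donation game, B=2, C=1, on the K4 profile."""
    return pairwise_tensor([(1.0, -1.0, 2.0, 0.0)], DegreeProfile((3,)))


@pytest.fixture(scope="session")
def vd_mixture_tensor(profile33):
    """Two volunteer's dilemmas, Bv1=1.05 / Bv2=10.05, Cv=1."""
    return additive_tensor(
        [volunteers_table(3, 1.05, 1.0), volunteers_table(3, 10.05, 1.0)],
        profile33,
    )


def compositions(k, max_parts=None):
    """All ordered positive compositions of k (optionally limited length)."""
    out = []

    def rec(remaining, parts):
        if remaining == 0:
            out.append(tuple(parts))
            return
        if max_parts is not None and len(parts) == max_parts:
            return
        for first in range(1, remaining + 1):
            rec(remaining - first, parts + [first])

    rec(k, [])
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
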