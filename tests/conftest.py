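from fractions import Fraction

import pytest

from majorules import (
    ModuleSpec,
    Rule,
    TwoNodeModel,
    yeast_network,
)

GENERIC = (Fraction(1, 3), Fraction(2, 7))
HALF = (Fraction(1, 2), Fraction(1, 2))


@pytest.fixture(scope="session")
def ip1():
    """Mutual activation with self-activations: the two-fixed-point model."""
    return TwoNodeModel(ModuleSpec(1, 1), ModuleSpec(1, 1))


@pytest.fixture(scope="session")
def ip2():
    """Self-inhibitions with symmetric cross: the period-2 model."""
    return TwoNodeModel(ModuleSpec(-1, 1), ModuleSpec(-1, 1))


@pytest.fixture(scope="session")
def ip3():
    """An asymmetric in-phase model: a regular chain."""
    return TwoNodeModel(ModuleSpec(1, 1), ModuleSpec(-1, -1))


@pytest.fixture(scope="session")
def op1():
    """Self-activations with asymmetric cross: the period-4 oscillator."""
    return TwoNodeModel(ModuleSpec(1, 1), ModuleSpec(1, -1))


@pytest.fixture(scope="session")
def yeast_pruned():
    return yeast_network("mr_pruned")


@pytest.fixture(scope="session")
def yeast_original():
    return yeast_network("original_with_selfloops")


@pytest.fixture(scope="session")
def yeast_revised():
    return yeast_network("revised")
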