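import math

import numpy as np
import pytest
from hypothesis import settings

import qalife as q

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

ROLES = ("g1", "p1", "g2", "p2")


@pytest.fixture
def roles():
    return ROLES


@pytest.fixture
def blank4():
    return q.StateVector.blank(ROLES)


@pytest.fixture
def exp1_state():
    """Final state of the two-individual interaction circuit."""
    return q.simulate(q.build_experiment("I"))


@pytest.fixture
def ghz_like():
    """cos(pi/3)|0000> + sin(pi/3)|1111> — one replicated lineage."""
    st = q.StateVector.blank(ROLES)
    st = q.create_individual(st, q.PrecursorSpec(alpha=math.pi / 3),
                             q.LivingUnit("g1", "p1"))
    return q.self_replicate(st, q.LivingUnit("g1", "p1"),
                            q.LivingUnit("g2", "p2"))


def assert_states_close(a, b, atol=1e-9):
    """Phase-insensitive state comparison."""
    assert a.overlap(b) == pytest.approx(1.0, abs=atol)
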