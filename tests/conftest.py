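import numpy as np
import pytest

from tmdimer.helices import (P75_SEQUENCE, P75_START, TRKA_SEQUENCE,
                             TRKA_START, build_ideal_helix)
from tmdimer.synthetic import (P75_INTERFACE, TRKA_INTERFACE,
                               gen_interface_fixture as make_interface_fixture)
from tmdimer.trajio import TwoHelixTrajectory


def make_two_helix_frame(offset=(10.0, 0.0, 0.0), rotate_b=None,
                         box: float = 200.0) -> TwoHelixTrajectory:
    """One frame of two ideal helices, B displaced (and optionally rotated)."""
    la, ra, na = build_ideal_helix(P75_SEQUENCE, P75_START)
    lb, rb, nb = build_ideal_helix(TRKA_SEQUENCE, TRKA_START)
    if rotate_b is not None:
        lb = rotate_b.apply(lb)
    cb = lb + np.asarray(offset, dtype=float)
    return TwoHelixTrajectory(la[None], cb[None], ra, rb, na, nb,
                              box=np.array([[box, box, box]]))


@pytest.fixture
def interface_fixture() -> TwoHelixTrajectory:
    return make_interface_fixture()


@pytest.fixture
def ideal_pair() -> TwoHelixTrajectory:
    return make_two_helix_frame()
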