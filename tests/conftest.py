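import numpy as np
import pytest

from fsmpath.calculators import ToyForceField
from fsmpath.fixtures import FixtureSpec, build, toyff_for
from fsmpath.geometry import Geometry
from fsmpath.internal_coords import build_ic_system


@pytest.fixture
def water():
    """Bent water-like triatomic (H-O-H, 104.5 deg)."""
    return build(FixtureSpec("bent-triatomic"))


@pytest.fixture
def butane_pair():
    """Anti (180 deg) / gauche (60 deg) united-atom butane endpoints."""
    return (
        build(FixtureSpec("butane-like", {"torsion": 180.0})),
        build(FixtureSpec("butane-like", {"torsion": 60.0})),
    )


@pytest.fixture
def twisted_pair():
    """Nonredundant 4-atom torsion pair (170 deg / 60 deg): no pruning."""
    return (
        build(FixtureSpec("butane-like", {"torsion": 170.0})),
        build(FixtureSpec("butane-like", {"torsion": 60.0})),
    )


@pytest.fixture
def twisted_icsys(twisted_pair):
    return build_ic_system(*twisted_pair)


@pytest.fixture
def butane_ff():
    return toyff_for("butane-like")


@pytest.fixture
def butane_calc(butane_ff):
    return ToyForceField(butane_ff)


@pytest.fixture
def particle():
    """One-pseudo-atom geometry factory for 2-D analytic surfaces."""

    def make(x, y):
        return Geometry(("X",), np.array([[x, y, 0.0]]))

    return make


def finite_difference_b(geometry, primitives, h=1e-5):
    """Central-difference Wilson B matrix: the independent oracle."""
    from fsmpath.internal_coords import measure

    n = 3 * geometry.natoms
    B = np.zeros((len(primitives), n))
    for j in range(n):
        xp = geometry.flat
        xm = geometry.flat
        xp[j] += h
        xm[j] -= h
        B[:, j] = (
            measure(geometry.with_coords(xp), primitives)
            - measure(geometry.with_coords(xm), primitives)
        ) / (2 * h)
    return B
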