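import numpy as np
import pytest

from aggrex.data import BOHR_IN_ANGSTROM
from aggrex.fixtures import ToyCrystalSpec, make_methanol, make_toy_crystal, make_water
from aggrex.structures import AtomSite, BondingScheme, Structure


@pytest.fixture
def methanol():
    return make_methanol()


@pytest.fixture
def water():
    return make_water()


@pytest.fixture
def rocksalt_bohr():
    """Rocksalt conventional cell with nearest-neighbor distance of 1 Bohr."""
    return make_toy_crystal(ToyCrystalSpec("rocksalt", a=2 * BOHR_IN_ANGSTROM))


@pytest.fixture
def herringbone():
    return make_toy_crystal(ToyCrystalSpec("herringbone-diatomic", a=4.0, b=4.0, c=6.0))


@pytest.fixture
def h2():
    return Structure([AtomSite("H", (0, 0, 0)), AtomSite("H", (0, 0, 0.74))],
                     bonding=BondingScheme("center", 1.0))


def rectangle_molecule(width=3.0, height=1.0, element="C"):
    corners = [(0, 0, 0), (width, 0, 0), (width, height, 0), (0, height, 0)]
    return Structure([AtomSite(element, c) for c in corners])


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
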