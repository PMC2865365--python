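import numpy as np
import pytest

from symcheck.lattice_symmetry import UnitCell
from symcheck.model import ScattererModel
from symcheck.symmetry_core import RationalSymOp, SpaceGroupDef
from symcheck.synthetic import make_underassigned_structure


@pytest.fixture(scope="session")
def p4_cell() -> UnitCell:
    return UnitCell(28.0, 28.0, 22.0)


@pytest.fixture(scope="session")
def p4_scatterers(p4_cell) -> ScattererModel:
    """~50 point scatterers arranged with an exact fourfold along z."""
    rng = np.random.default_rng(11)
    four = RationalSymOp.from_triplet("-y,x,z")
    asu = rng.random((12, 3)) * [0.3, 0.3, 1.0] + [0.08, 0.55, 0.0]
    pts = [asu]
    op = four
    for _ in range(3):
        pts.append(np.mod(op.apply(asu), 1.0))
        op = op * four
    return ScattererModel(p4_cell, np.vstack(pts))


@pytest.fixture(scope="session")
def p4_as_p1():
    """Perfect P4 toy crystal presented in P1 (no noise, no shift)."""
    return make_underassigned_structure(
        "P4", chains_per_asu=2, subgroup="P1", seed=5
    )


@pytest.fixture(scope="session")
def p4_as_p1_shifted():
    return make_underassigned_structure(
        "P4", chains_per_asu=2, subgroup="P1", seed=5,
        origin_shift=(0.11, 0.23, 0.0),
    )


def sg(symbol: str) -> SpaceGroupDef:
    return SpaceGroupDef.from_symbol(symbol)
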