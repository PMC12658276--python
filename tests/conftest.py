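import numpy as np
import pytest

from membpka.constants import PhysicalConstants
from membpka.structure_io import AtomRecord, StructureFrame


@pytest.fixture(scope="session")
def const_ambient() -> PhysicalConstants:
    """Ambient-temperature constants without mobile-ion screening."""
    return PhysicalConstants(temperature=298.15, ionic_strength=0.0)


@pytest.fixture(scope="session")
def const_saline() -> PhysicalConstants:
    """Ambient-temperature constants at 0.15 M 1:1 electrolyte."""
    return PhysicalConstants(temperature=298.15, ionic_strength=0.15)


@pytest.fixture
def point_charge_frame() -> StructureFrame:
    """A single radius-free unit charge at the origin (pure solvent grid)."""
    return StructureFrame(
        [AtomRecord("Q", "C", "DUM", 1, "A", np.zeros(3), 1.0, 0.0)]
    )


def make_atom(name="X", element="C", resname="DUM", resid=1, chain="A",
              pos=(0.0, 0.0, 0.0), charge=0.0, radius=1.5) -> AtomRecord:
    return AtomRecord(name, element, resname, resid, chain, np.asarray(pos, float),
                      charge, radius)
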