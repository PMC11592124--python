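import pytest

from celltherm import (
    CellGeometry,
    ThermoEnvironment,
    load_reference_ion_table,
)


@pytest.fixture(scope="session")
def reference_ions():
    return load_reference_ion_table()


@pytest.fixture(scope="session")
def sodium(reference_ions):
    return next(i for i in reference_ions if i.name == "Na+")


@pytest.fixture
def geometry():
    """10 µm radius, 4 nm membrane: the worked-example cell."""
    return CellGeometry(radius=10e-6, membrane_thickness=4e-9)


@pytest.fixture
def environment():
    return ThermoEnvironment()
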