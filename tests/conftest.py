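import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from spinaltau import (
    AssemblyModel,
    FluidProperties,
    ManometerSpec,
    NeedleSpec,
    load_fixture,
)

#: Bore of the bench manometer, cm.
BENCH_BORE = 0.37


@pytest.fixture(scope="session")
def unit_fluid():
    return FluidProperties(density=1.0, dynamic_viscosity=1.0e-5)


@pytest.fixture(scope="session")
def manometer():
    return ManometerSpec(bore_diameter=BENCH_BORE)


@pytest.fixture(scope="session")
def pajunk_assembly(unit_fluid, manometer):
    """22G Pajunk Sprotte-like assembly: R = 667.9, tau ~ 71.8 s."""
    needle = NeedleSpec(name="22G Pajunk Sprotte", gauge="22G", length=9.0, resistance=667.9)
    return AssemblyModel(needle=needle, manometer=manometer, fluid=unit_fluid)


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")
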