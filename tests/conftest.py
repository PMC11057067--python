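import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungstress import (
    InterfacePair,
    PatientMechanics,
    SimulationConfig,
    UnitField,
    VentilationCycle,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def vignette_cycle() -> VentilationCycle:
    """The worked ventilation cycle: PEEP 5, dP 10 cmH2O, VT 0.4 L, f 20/min."""
    return VentilationCycle(peep=5.0, driving_pressure=10.0, tidal_volume=0.4, frequency=20.0)


@pytest.fixture
def vignette_mechanics(vignette_cycle) -> PatientMechanics:
    """Worked patient: C_obs 20, C_pred 80 mL/cmH2O (baby-lung fraction 0.25)."""
    return PatientMechanics(c_obs=20.0, c_pred=80.0, cycle=vignette_cycle)


@pytest.fixture
def tenfold_pair() -> InterfacePair:
    """Compliance interface at the histological extreme, C1/C2 = 10."""
    return InterfacePair(c1=10.0, c2=1.0)


@pytest.fixture
def checkerboard_field() -> UnitField:
    """4x4 checkerboard: every one of the 24 edges is heterogeneous."""
    labels = np.indices((4, 4)).sum(axis=0) % 2
    compliances = np.where(labels == 1, 0.25, 2.0)
    return UnitField(labels=labels.astype(np.int8), compliances=compliances)


@pytest.fixture
def segregated_cfg() -> SimulationConfig:
    """4x4 grid, half abnormal, fully segregated."""
    return SimulationConfig(nx=4, ny=4, abnormal_fraction=0.5, dispersal=0.0, seed=3)
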