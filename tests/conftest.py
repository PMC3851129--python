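import numpy as np
import pytest

from glusim.biomass_model import PrecursorCoefficient
from glusim.model_core import (
    ModelDefinition,
    RateLaw,
    Reaction,
    Species,
    build_network,
)
from glusim.simulation_engine import GrowthProfile


@pytest.fixture(scope="session")
def reference():
    """Curated reference model, built once per session."""
    from glusim.reference_model import build_reference_model

    network, profile, biomass = build_reference_model()
    return network, profile, biomass


@pytest.fixture(scope="session")
def reference_baseline(reference):
    """Baseline reference time course and yield, computed once."""
    from glusim.reference_model import reference_config
    from glusim.simulation_engine import simulate, yield_metric

    network, profile, _ = reference
    config = reference_config()
    tc = simulate(network, profile, config)
    return tc, yield_metric(tc), config


def chain_network(k1: float = 1.0, k2: float = 1.0):
    """Closed A -> B -> C chain, uncatalysed mass action, no expression."""
    defn = ModelDefinition(
        species=[
            Species(id="A", concentration=1.0),
            Species(id="B", concentration=0.0),
            Species(id="C", concentration=0.0),
        ],
        reactions=[
            Reaction(
                id="r1",
                stoichiometry={"A": -1, "B": 1},
                rate_law=RateLaw(form="mass_action", kcat=k1),
            ),
            Reaction(
                id="r2",
                stoichiometry={"B": -1, "C": 1},
                rate_law=RateLaw(form="mass_action", kcat=k2),
            ),
        ],
    )
    return build_network(defn)


@pytest.fixture
def toy_chain():
    return chain_network()


@pytest.fixture
def flat_profile():
    """Constant biomass density: mu(t) = 0 everywhere."""
    return GrowthProfile(times=np.array([0.0, 1000.0]), densities=np.array([1.0, 1.0]))


@pytest.fixture
def valid_biomass_table():
    return [
        PrecursorCoefficient("OAA", 1.0),
        PrecursorCoefficient("FUM", 0.2),
        PrecursorCoefficient("S7P", 0.01),
    ]
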