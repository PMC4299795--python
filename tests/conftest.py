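import numpy as np
import pytest
from hypothesis import settings

from paleoerv.simulate import (Degradation, InsertSpec, SimulationConfig,
                               simulate_genome)
from paleoerv.detect import call_proviruses

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mixed_build():
    """One genome with lightly degraded members of all four classes plus a
    solo LTR and a capture-bearing provirus."""
    specs = [
        InsertSpec("ERV1", 0.02, Degradation(0.01), family=0),
        InsertSpec("ERV1", 0.04, Degradation(0.01), family=0),
        InsertSpec("ERV1", 0.03, Degradation(0.01), family=0),
        InsertSpec("ERV2", 0.03, Degradation(0.01), family=1),
        InsertSpec("ERV2", 0.05, Degradation(0.01), family=1),
        InsertSpec("ERV2", 0.02, Degradation(0.01), family=1),
        InsertSpec("ERV3", 0.02, Degradation(0.01), family=2),
        InsertSpec("ERV3", 0.04, Degradation(0.01), family=2),
        InsertSpec("ERV3", 0.03, Degradation(0.01), family=2),
        InsertSpec("ERV4", 0.05, Degradation(0.01), family=3),
        InsertSpec("ERV4", 0.02, Degradation(0.01), family=3),
        InsertSpec("ERV4", 0.03, Degradation(0.01), family=3),
        InsertSpec("ERV1", 0.03, family=0, solo=True),
        InsertSpec("ERV4", 0.02, Degradation(0.005),
                   capture="between_pol_env", family=3),
    ]
    return simulate_genome(SimulationConfig(
        600_000, insert_specs=specs, seed=2024), species="crocsim")


@pytest.fixture(scope="session")
def mixed_calls(mixed_build):
    return call_proviruses(mixed_build)


def truth_near(build, call):
    return min(build.truth, key=lambda t: abs(t.start - call.start))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
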