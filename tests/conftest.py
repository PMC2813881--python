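import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_model():
    from rnafoot import build_toy_structure

    return build_toy_structure(540, seed=1)


@pytest.fixture(scope="session")
def free_bound_reactivity(toy_model):
    """Normalized (unsmoothed) free and bound profiles from one seeded run."""
    from rnafoot import SimulationConfig, normalize_reactivity, simulate_cleavage, subtract_background

    out = []
    for state, seed in (("free", 101), ("bound", 202)):
        raw = simulate_cleavage(toy_model, state, SimulationConfig(seed=seed))
        out.append(normalize_reactivity(subtract_background(raw)))
    return tuple(out)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
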