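import numpy as np
import pytest

import whorfnet as w


@pytest.fixture(scope="session")
def concrete_set() -> w.GroundingSet:
    return w.make_grounding_set(w.PatternSpec(semantic_type="concrete", seed=11))


@pytest.fixture(scope="session")
def abstract_set() -> w.GroundingSet:
    return w.make_grounding_set(w.PatternSpec(semantic_type="abstract", seed=11))


@pytest.fixture(scope="session")
def wordforms() -> w.WordformSet:
    return w.make_wordform_set(10, seed=11)


@pytest.fixture(scope="session")
def network() -> w.Network:
    """One default-parameter network shared by read-only tests."""
    return w.build_network(w.ModelParams(), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
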