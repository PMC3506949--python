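import pytest

from relatch import estimate_reference
from relatch.fixtures import TOY_KINDS, make_synthetic_reference_data, make_toy_network

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # hypothesis is optional; property tests skip without it
    pass


@pytest.fixture(scope="session")
def toy_models():
    return {kind: make_toy_network(kind) for kind in TOY_KINDS}


@pytest.fixture(scope="session")
def toy_scenarios(toy_models):
    return {
        kind: make_synthetic_reference_data(model, seed=0, noise_sigma=0.0)
        for kind, model in toy_models.items()
    }


@pytest.fixture(scope="session")
def toy_references(toy_scenarios):
    """Solved noiseless reference states, one per toy topology."""
    out = {}
    for kind, sc in toy_scenarios.items():
        ref = estimate_reference(sc.model, sc.mfa, sc.expression, sc.physiology)
        assert ref.ok, f"reference for {kind} did not solve"
        out[kind] = ref
    return out


@pytest.fixture(scope="session")
def diamond(toy_scenarios, toy_references):
    sc = toy_scenarios["diamond"]
    return sc.model, sc, toy_references["diamond"]
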