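import pytest

from finflux.synthetic_data import ToyModelSpec, generate_toy_model


@pytest.fixture(scope="session")
def toy_model():
    """Default synthetic core model (anaerobic lactate route included)."""
    return generate_toy_model()


@pytest.fixture(scope="session")
def aerobe_model():
    """Obligate-aerobe variant used by the canonical hypoxia sweep."""
    return generate_toy_model(ToyModelSpec(include_anaerobic_route=False))
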