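import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fuzzydea.de_model import fit_hyperbolas
from fuzzydea.simulate import example_possibility_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_table():
    """The bundled worked example: 5 reads, 3 paralog-like genes, 11 hits."""
    return example_possibility_table()


@pytest.fixture(scope="session")
def null_model():
    """Envelope fitted on a null fold-change cloud (flat scatter sd 0.25)."""
    rng = np.random.default_rng(7)
    m = np.exp(rng.uniform(np.log(1.5), np.log(2000.0), 4000))
    fc = rng.normal(0.0, 0.25, m.size)
    return fit_hyperbolas(np.column_stack([m, fc]), q=0.99, min_m=1.0)
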