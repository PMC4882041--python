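import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from phytomacro.model import SamplerConfig
from phytomacro.synthetic import generate_dataset, tiny_design


#: small-but-real sampler settings for unit tests (same burn-in/thinning
#: fractions as the reference preset)
FAST = SamplerConfig(n_chains=2, n_iterations=2000, thin=5, seed=11)


@pytest.fixture(scope="session")
def tiny_table():
    """3 phyla x 4 species x 5 obs per pool, with protein-method mixture."""
    table, truth = generate_dataset(tiny_design(seed=7))
    return table, truth


@pytest.fixture
def fast_config():
    return FAST
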