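import random

import pytest
from hypothesis import HealthCheck, settings, strategies as st

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

#: strategy for nonempty DNA strings
dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def small_genome():
    from minitig.synthetic_fixtures import random_genome

    return random_genome(800, 42)
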