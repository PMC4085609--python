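"""Shared test configuration.

Hypothesis is run derandomized (fixed example generation) so the suite
is deterministic run-to-run; deadlines are disabled because several
properties align kilobase-scale sequences.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repeatscape",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatscape")


@pytest.fixture
def rng():
    return np.random.default_rng(20140707)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
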