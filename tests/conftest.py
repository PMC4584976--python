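import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phylocap.locus_screening import LocusAlignment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150917)


@pytest.fixture
def toy_alignment():
    """Four sequences, three columns: AAAA / AAAT / AATT by column."""
    return LocusAlignment(
        "toy",
        {
            "s1": "AAA",
            "s2": "AAA",
            "s3": "AAT",
            "s4": "ATT",
        },
    )
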