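import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20110720)


@pytest.fixture
def micro_alignment():
    """Two alleles around a compound TA/CA locus in columns 3-10."""
    from ssralign import Alignment

    return Alignment(("x", "y"), ("GGTATACACAGG", "GGTATATACAGG"))
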