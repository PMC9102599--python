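import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20220513)


@pytest.fixture
def small_quantized_table():
    """A tiny hand-built quantized table: classes {1,1,2,2,2,3} in one
    condition plus two golgi-compartment rows in another."""
    from wpbribbon import LengthTable, quantize_lengths

    lengths = [0.58, 0.60, 1.15, 1.16, 1.10, 1.73, 0.55, 1.12]
    table = LengthTable.from_records(
        lengths,
        condition="control",
        compartment=["cytoplasm"] * 6 + ["golgi"] * 2,
    )
    return quantize_lengths(table, 0.576)
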