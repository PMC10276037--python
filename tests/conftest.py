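import numpy as np
import pytest

from porediff.geometry import (
    GeneratorConfigA,
    GeneratorConfigB,
    PorousSample,
    generate_type_a,
    generate_type_b,
)


@pytest.fixture(scope="session")
def all_fluid_16():
    return PorousSample(np.ones((16, 16), dtype=bool))


@pytest.fixture(scope="session")
def sample_a_small():
    return generate_type_a(32, GeneratorConfigA(target_porosity=0.6), seed=3)


@pytest.fixture(scope="session")
def sample_b_small():
    return generate_type_b(
        32, GeneratorConfigB(n_points=8, target_porosity=0.4), seed=5
    )
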