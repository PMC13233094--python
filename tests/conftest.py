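import numpy as np
import pytest

from curriculumnet import make_task


@pytest.fixture(scope="session")
def task2():
    """Canonical 2-d task geometry."""
    return make_task(2, canonical=True)


@pytest.fixture(scope="session")
def task10():
    """Seeded random orthonormal geometry in 10 dimensions."""
    return make_task(10, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
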