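import pytest

from boolclock import builtin_model
from boolclock.synth import SyntheticSpec, generate

MODEL_NAMES = [
    "neurospora_1loop",
    "neurospora_2loop",
    "arabidopsis_2loop",
    "arabidopsis_3loop",
]


@pytest.fixture(scope="session", params=MODEL_NAMES)
def any_model(request):
    return builtin_model(request.param)


@pytest.fixture(scope="session")
def n1():
    return builtin_model("neurospora_1loop")


@pytest.fixture(scope="session")
def n2():
    return builtin_model("neurospora_2loop")


@pytest.fixture(scope="session")
def a2():
    return builtin_model("arabidopsis_2loop")


@pytest.fixture(scope="session")
def a3():
    return builtin_model("arabidopsis_3loop")


@pytest.fixture(scope="session")
def n1_noise_free():
    """Noise-free LD+DD dataset self-generated by the 1-loop circuit."""
    spec = builtin_model("neurospora_1loop")
    return generate(SyntheticSpec(model=spec, sigma=0.0, seed=1))


@pytest.fixture(scope="session")
def n2_noise_free():
    spec = builtin_model("neurospora_2loop")
    return generate(SyntheticSpec(model=spec, sigma=0.0, seed=1))
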