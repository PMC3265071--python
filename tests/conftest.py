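import hypothesis
import numpy as np
import pytest

from estrorisk import default_config, default_suite
from estrorisk.population import BmiDistribution

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def suite():
    """ModelSuite with the shipped default coefficients."""
    return default_suite()


@pytest.fixture(scope="session")
def standin_dist():
    """The packaged synthetic postmenopausal BMI distribution."""
    return BmiDistribution.from_spec(default_config()["bmi_distribution"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20120116)


def sig_round(x: float, n: int) -> float:
    """Round to n significant figures."""
    return float(f"{x:.{n}g}")
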