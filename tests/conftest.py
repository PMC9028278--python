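import numpy as np
import pytest
from hypothesis import settings

from cyclospot import CyclicPeptide, SynthConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def jb1():
    return CyclicPeptide("JB1", "CYAAPLKPAKSC")


@pytest.fixture(scope="session")
def somatostatin():
    return CyclicPeptide(
        "somatostatin", "AGCKNFFWKTFTSC", topology="disulfide", disulfide_pair=(3, 14)
    )


@pytest.fixture(scope="session")
def jb1_synth_pair(jb1):
    """One small synthetic analyte/control pair with the Ser opening planted."""
    config = SynthConfig(parent=jb1, true_opening_sites=((11, 1.0),), seed=42)
    analyte, control, truth = generate(config)
    return analyte, control, truth, config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
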