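import numpy as np
import pytest
from hypothesis import settings

from knobminer import RepertoireConfig, builtin_germlines, simulate_repertoire

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def germlines():
    return builtin_germlines()


@pytest.fixture(scope="session")
def core_aa(germlines):
    from Bio.Seq import Seq
    return str(Seq(germlines.ighd82_core.seq).translate())


@pytest.fixture(scope="session")
def small_repertoire(germlines):
    """300-clone repertoire with a tenth ultralong, default SHM."""
    config = RepertoireConfig(n_clones=300, ultralong_fraction=0.1, seed=42)
    return simulate_repertoire(germlines, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
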