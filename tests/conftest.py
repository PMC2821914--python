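import numpy as np
import pytest

from synucleag import synthetic


@pytest.fixture(scope="session")
def templates():
    return synthetic.example_templates()


@pytest.fixture(scope="session")
def protein():
    return synthetic.gen_protein_conformer(140, synthetic.SynthConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
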