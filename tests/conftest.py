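import pytest

from compoundalign import examples
from compoundalign.config import MatchConfig
from compoundalign.synthetic_data import SynthSpec, generate_models


@pytest.fixture
def config():
    return MatchConfig()


@pytest.fixture
def hp_fma_pato():
    return examples.hp_fma_pato()


@pytest.fixture
def mp_uberon_pato():
    return examples.mp_uberon_pato()


@pytest.fixture
def mp_cl_pato():
    return examples.mp_cl_pato()


@pytest.fixture
def small_triple():
    """A small noisy synthetic triple plus its embedded ground truth."""
    return generate_models(
        SynthSpec(n_source=40, anatomy_vocab_size=40, quality_vocab_size=12,
                  p_add=0.3, p_var=0.2, p_syn=0.2, seed=11)
    )
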