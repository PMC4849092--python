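import numpy as np
import pytest

from corblosum import Block, ScenarioSpec, VariantConfig
from corblosum.simulate import generate_scenario


@pytest.fixture
def toy_block():
    """Width-4 block whose clustering behaviour is easy to enumerate."""
    return Block("toy", 4, [("s1", "AAAA"), ("s2", "AAAB"), ("s3", "ABBB")])


@pytest.fixture
def corblosum62():
    return VariantConfig.for_variant("corblosum", 62)


@pytest.fixture
def two_superfamily_scenario():
    """Sizes {2, 3} with planted fractions {1.0, 0.5} -> Q_quad = 0.75."""
    spec = ScenarioSpec(sizes=(2, 3), tp_fractions=(1.0, 0.5),
                        n_false_positives=4, seed=11)
    return generate_scenario(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20160427)
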