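import numpy as np
import pytest

from pepscan import PeptideSequence, datasets


@pytest.fixture
def wild_type() -> PeptideSequence:
    return datasets.WILD_TYPE


@pytest.fixture
def mtp1() -> PeptideSequence:
    return datasets.MTP1


@pytest.fixture
def mtp2() -> PeptideSequence:
    return datasets.MTP2


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160616)
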