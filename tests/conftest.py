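import numpy as np
import pytest

from studyfactories import (
    cousin_pedigree,
    fba_fixture_bundle,
    three_generation_pedigree,
    trio_pedigree,
)


@pytest.fixture
def trio():
    return trio_pedigree()


@pytest.fixture
def three_gen():
    return three_generation_pedigree()


@pytest.fixture
def cousins():
    return cousin_pedigree()


@pytest.fixture
def fba_bundle():
    return fba_fixture_bundle()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
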