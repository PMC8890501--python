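import numpy as np
import pytest
from hypothesis import settings

from ribolandscape import GeneratorParams, LibrarySpec

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec() -> LibrarySpec:
    return LibrarySpec()


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams()


@pytest.fixture(scope="session")
def toy_spec2() -> LibrarySpec:
    """Two variable positions (16 genotypes) in a short reference."""
    return LibrarySpec(
        reference_sequence="GGACAUCGGU",
        variable_positions=(2, 6),
        mg_levels=(1.0, 4.0, 16.0, 48.0),
        replicates=3,
    )


@pytest.fixture(scope="session")
def toy_spec1() -> LibrarySpec:
    """One variable position (4 genotypes); wild-type allele is A."""
    return LibrarySpec(
        reference_sequence="GGAACU",
        variable_positions=(2,),
        mg_levels=(1.0, 8.0),
        replicates=2,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
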