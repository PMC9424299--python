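import numpy as np
import pytest

from dfstates.core_io import AnalysisConfig, Parcellation
from dfstates.synthetic import synthetic_parcellation


@pytest.fixture(scope="session")
def parcellation() -> Parcellation:
    """48 cortical regions (8 networks x 6, all homotopically paired) plus
    12 subcortical regions (6 nuclei, 6 limbic)."""
    return synthetic_parcellation()


@pytest.fixture(scope="session")
def tiny_parcellation() -> Parcellation:
    """Two homotopic regions in one network plus one subcortical region."""
    return Parcellation(
        labels=("A_L", "A_R", "thal"),
        hemisphere=("L", "R", "none"),
        network=("NETA", "NETA", "nuclei"),
        is_subcortical=(False, False, True),
        homotopic_partner=(1, 0, -1),
    )


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
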