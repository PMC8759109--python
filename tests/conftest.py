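import warnings

import pytest

from pdacrisk.cohorts import build_analysis_datasets
from pdacrisk.simulate import SimConfig, generate_population


@pytest.fixture(scope="session")
def emr_small():
    """A 1,500-subject simulated EMR population shared across tests."""
    return generate_population(SimConfig(n_subjects=1500, seed=11))


@pytest.fixture(scope="session")
def built_small(emr_small):
    """Analysis datasets built from the shared small population."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_analysis_datasets(emr_small)
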