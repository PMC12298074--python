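import warnings

import pytest

from prillopt.dataset_io import load_reference_dataset
from prillopt.desirability_ga import load_reference_desirability


@pytest.fixture(scope="session")
def reference_dataset():
    return load_reference_dataset()


@pytest.fixture(scope="session")
def reference_specs():
    return load_reference_desirability()


@pytest.fixture(autouse=True)
def _silence_out_of_range_warnings():
    # out-of-calibrated-range desirability warnings are expected in sweeps
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
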