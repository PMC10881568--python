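import numpy as np
import pytest

from httcag.synthetic_cohort import AlleleModel, cohort_spec_from_counts
from httcag.trace_sim import TraceParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240221)


@pytest.fixture(scope="session")
def default_model():
    return AlleleModel.default()


@pytest.fixture(scope="session")
def default_trace_params():
    return TraceParams()


@pytest.fixture
def tiny_spec():
    """A small two-group cohort spec with one forced intermediate carrier."""
    return cohort_spec_from_counts(
        [("controls", 30, 2), ("MLH1", 10, 1)], seed=99
    )
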