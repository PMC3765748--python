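import numpy as np
import pytest

from painhub import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


TINY = dict(n_per_group=2, grid_shape=(14, 14, 10), n_timepoints=40, seed=7)


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(**TINY)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory, tiny_spec):
    """A 2+2-subject cohort on a small grid, generated once per session."""
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(tiny_spec, out)
    return out
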