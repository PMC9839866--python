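import numpy as np
import pytest

from sigpep.synthetic_data import SynthParams, generate_cohort, sample_cohort


@pytest.fixture(scope="session")
def small_params():
    return SynthParams(n_sps=80, n_duplicates=8, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """80 SPs (8 duplicate sequences) with ground truth."""
    return sample_cohort(small_params)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_params):
    """Generated cohort files on disk (FASTA + annotation TSV)."""
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(small_params, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
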