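import numpy as np
import pytest

from chromdiff.simulate import CohortConfig, generate_cohort, write_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the study conditions: 6 pairs, 2000 shared peaks,
    100 case- and 100 control-specific peaks at 3-fold, fixed seed."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """No-effect cohort: same conditions with zero planted specific peaks."""
    return generate_cohort(CohortConfig(seed=11, n_case_specific=0,
                                        n_control_specific=0))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(
        seed=5, n_shared_peaks=400, n_case_specific=40, n_control_specific=40,
        n_het_variants_in_peaks=60, n_genes=120, n_up_genes=15,
        n_down_genes=15))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_cohort):
    d = tmp_path_factory.mktemp("cohort_fixture")
    write_cohort(small_cohort, d)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(0)
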