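import numpy as np
import pytest

from lungvox import StudyConfig, run_baseline, run_longitudinal, simulate_cohort
from lungvox.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def he3():
    from lungvox.protocols import he3_protocol

    return he3_protocol()


@pytest.fixture(scope="session")
def xe129():
    from lungvox.protocols import xe129_protocol

    return xe129_protocol()


@pytest.fixture(scope="session")
def phantom():
    """One default-condition phantom subject (5 mm misalignment, SNR 20)."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def cohort():
    """Two-subject phantom cohort for the end-to-end analyses."""
    return simulate_cohort(2, base_seed=11)


@pytest.fixture(scope="session")
def study_config(tmp_path_factory):
    return StudyConfig(seed=11, out_dir=str(tmp_path_factory.mktemp("study")))


@pytest.fixture(scope="session")
def baseline_report(cohort, study_config):
    """Full baseline run (fit + indirect co-registration + statistics)."""
    return run_baseline(cohort, study_config)


@pytest.fixture(scope="session")
def longitudinal_report(baseline_report, cohort, study_config):
    return run_longitudinal(baseline_report, cohort, study_config)
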