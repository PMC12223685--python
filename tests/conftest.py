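import pytest

from narrsim.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def calibrated_cohort():
    """20k-record cohort at the packaged default calibration (shared by the
    calibration and split-invariant suites; generation takes a few seconds)."""
    return generate_cohort(default_config(n_records=20000, seed=20150))


@pytest.fixture(scope="session")
def small_cohort():
    """2k-record cohort for harness-level tests."""
    cfg = default_config(n_records=2000, seed=7)
    return generate_cohort(cfg)
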