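import pytest

from vitalink import LinkageConfig, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def link_cfg() -> LinkageConfig:
    return LinkageConfig(rng_seed=17)


@pytest.fixture(scope="session")
def noisy_cohort():
    """A small default-noise cohort shared across read-only tests."""
    cfg = SimulationConfig(n_deliveries=400, rng_seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort with every error and withholding probability at zero."""
    cfg = SimulationConfig(n_deliveries=400, rng_seed=7,
                           p_mother_unlinked=0, p_infant_unlinked=0,
                           p_dob_transposed=0, p_field_missing=0, p_zip_error=0)
    return cfg, simulate_cohort(cfg)
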