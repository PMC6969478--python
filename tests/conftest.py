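import pytest

from gzmorph import GeneratorConfig, generate_cohort, generate_larva


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def noiseless_config():
    """All observation/staging noise and size variation switched off."""
    return GeneratorConfig(stage_noise_stripes=0, hatch_jitter_min=0.0,
                           phase_jitter_frac=0.0, size_cv=0.0)


@pytest.fixture(scope="session")
def field_t0():
    return generate_larva(0.0, seed=0)


@pytest.fixture(scope="session")
def field_t2():
    return generate_larva(2.05, seed=1)


@pytest.fixture(scope="session")
def fields_50():
    """Fifty replicate hatchling fields for pooled label-frequency checks."""
    return [generate_larva(0.05, seed=s) for s in range(50)]


@pytest.fixture(scope="session")
def measured_cohort():
    """The default staged cohort: 25 larvae/h, hourly 0-18 h, full measures."""
    return generate_cohort(seed=0, measure=True)
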