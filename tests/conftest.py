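import pytest

import cdvar


@pytest.fixture(scope="session")
def default_config():
    return cdvar.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    return cdvar.generate_cohort(default_config)


@pytest.fixture(scope="session")
def samples(cohort, default_config):
    return cdvar.generate_samples(cohort, default_config)


@pytest.fixture(scope="session")
def processed(samples):
    return cdvar.process_samples(samples)


@pytest.fixture(scope="session")
def geography(cohort, default_config):
    return cdvar.generate_geography(cohort, default_config)


@pytest.fixture(scope="session")
def contaminants(default_config):
    return cdvar.generate_contaminant_table(default_config)


@pytest.fixture(scope="session")
def ffq(cohort, contaminants, default_config):
    return cdvar.generate_ffq(cohort, contaminants, default_config)


@pytest.fixture(scope="session")
def profiles(cohort, geography, ffq, contaminants):
    return cdvar.build_exposure_profiles(cohort, geography, ffq, contaminants)


@pytest.fixture(scope="session")
def model_frame(processed, cohort, profiles):
    return cdvar.build_model_frame(processed, cohort, profiles)
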