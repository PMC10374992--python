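import dataclasses

import pytest

from strokecohort import classify_cohort, default_config, generate_cohort


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def cohort(cfg):
    return generate_cohort(cfg, 4000, seed=11)


@pytest.fixture(scope="session")
def full_workup_cohort(cfg):
    full = dataclasses.replace(cfg, availability_probs=(1.0, 1.0, 1.0))
    return generate_cohort(full, 4000, seed=11)


@pytest.fixture(scope="session")
def assignments(cohort):
    a, _ = classify_cohort(cohort)
    return a
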