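import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from sonar import SimulationConfig, SubgroupSchema, make_hard_concepts, simulate
from sonar import pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


SMALL_CONFIG = dataclasses.replace(
    make_hard_concepts(SimulationConfig(seed=42), 0.3),
    n_concepts=12,
    n_distractors=8,
    patients_per_cohort=200,
)


@pytest.fixture(scope="session")
def schema():
    return SubgroupSchema()


@pytest.fixture(scope="session")
def small_dataset():
    """A small 3-cohort dataset shared by tests that only read it."""
    return simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_cohorts(small_dataset):
    return {
        cid: pipeline.prepare_cohort(
            small_dataset.records(cid),
            small_dataset.patient_table(cid),
            SMALL_CONFIG.schema,
        )
        for cid in small_dataset.cohort_ids
    }
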