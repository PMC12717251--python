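import pytest

from perioeval import (
    PredictorProfile,
    default_cohort_spec,
    default_label_set,
    generate_cohort,
)


@pytest.fixture(scope="session")
def label_set():
    return default_label_set()


@pytest.fixture(scope="session")
def small_cohort():
    """Fixed 40-case dual-center cohort with schematic records."""
    spec = default_cohort_spec(n_patients=40, seed=1234)
    return generate_cohort(spec, with_records=True)


@pytest.fixture(scope="session")
def small_gold(small_cohort):
    return {c.case_id: list(c.truth) for c in small_cohort}


@pytest.fixture()
def perfect_profile():
    return PredictorProfile(
        sensitivity=1.0, false_positive_rate=0.0, severity_confusion=0.0, run_flip=0.0
    )
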