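"""Shared fixtures: synthetic cohorts reused across test modules."""

import numpy as np
import pytest

import physiotype as pt
from physiotype.io import RunConfig


@pytest.fixture(scope="session")
def default_templates():
    return pt.make_default_templates()


@pytest.fixture(scope="session")
def cohort600(default_templates):
    """The reference synthetic cohort: n=600, default separation, seed 1."""
    return pt.generate_cohort(default_templates, n=600, seed=1)


@pytest.fixture(scope="session")
def features600(cohort600):
    """Preprocessed 600 x 36 feature matrix plus generator truth labels."""
    series = pt.cohort_to_series(cohort600)
    res = pt.preprocess_cohort(series, RunConfig(seed=1))
    truth = {e.encounter_id: e.true_label for e in cohort600}
    labels = np.array([truth[i] for i in res.features.encounter_ids])
    return res.features, labels


@pytest.fixture(scope="session")
def small_features(default_templates):
    """A small cohort (n=200, seed 3) for the cheaper characterization tests."""
    cohort = pt.generate_cohort(default_templates, n=200, seed=3)
    series = pt.cohort_to_series(cohort)
    res = pt.preprocess_cohort(series, RunConfig(seed=3))
    truth = {e.encounter_id: e.true_label for e in cohort}
    labels = np.array([truth[i] for i in res.features.encounter_ids])
    return res.features, labels
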