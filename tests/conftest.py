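import numpy as np
import pytest

from edgeentropy.core import CohortVector, kde_probability_vector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(values, gene="G1", label="reference"):
    values = np.asarray(values, dtype=float)
    ids = [f"{label[0]}{i}" for i in range(len(values))]
    return CohortVector(gene_id=gene, values=values, cohort_label=label, sample_ids=ids)


def make_profile(values, gene="G1", label="reference"):
    return kde_probability_vector(make_cohort(values, gene, label))


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture
def profile_factory():
    return make_profile
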