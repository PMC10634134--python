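import pytest

from histborrow.cohorts import (CovariateModel, reconstruct_treatable_cohort,
                                worked_example_suite)
from histborrow.likelihoods import ModelSpec, pooled_centering


@pytest.fixture(scope="session")
def covariate_model():
    return CovariateModel()


@pytest.fixture(scope="session")
def cohort():
    """The reconstructed 179-patient historical cohort (default seed)."""
    return reconstruct_treatable_cohort()


@pytest.fixture(scope="session")
def cohort_summary(cohort):
    return cohort.summarize()


@pytest.fixture(scope="session")
def suite():
    """The eight worked-example datasets keyed by PMX deaths."""
    return worked_example_suite()


@pytest.fixture(scope="session")
def unadj():
    return ModelSpec(adjusted=False)


@pytest.fixture(scope="session")
def adj(suite):
    """Adjusted model spec centered at the shared worked-example APACHE mean."""
    return ModelSpec(adjusted=True, centering=pooled_centering(suite[44]))
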