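import pytest

from trnadyn import CohortSpec, generate_cohort, pipeline


@pytest.fixture(scope="session")
def cohort():
    """One deterministic synthetic cohort shared across the suite."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def aligned_cohort(cohort):
    """The same cohort pushed through template annotation and alignment."""
    anns = pipeline.annotate_all(cohort.genes)
    aligs = pipeline.align_all(cohort.genes, anns)
    return cohort, anns, aligs
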