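import pytest

from nsclc_staging import CohortConfig, generate_cohort, render_text
from nsclc_staging.experiments import make_signature_documents


@pytest.fixture(scope="session")
def small_cohort():
    """400 mixed-stage records, seeded."""
    return generate_cohort(CohortConfig(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def small_corpus(small_cohort):
    return [render_text(r) for r in small_cohort]


def make_separable_docs(n_pos, n_neg, seed, **kwargs):
    """Separable toy document matrices (planted-signature generator)."""
    return make_signature_documents(n_pos, n_neg, seed, **kwargs)
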