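import numpy as np
import pytest

from toxmark import CohortConfig, build_dataset, simulate_cohort
from toxmark.simulate import SYMPTOM


@pytest.fixture(scope="session")
def small_cohort():
    """Small but non-trivial cohort: 12 drugs x 10 samples, 150 genes,
    6 planted markers with a strong per-grade effect."""
    cfg = CohortConfig(
        n_drugs=12,
        samples_per_drug=10,
        n_genes=150,
        n_markers=6,
        effect_size=0.9,
        frac_toxic_drugs=0.5,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    expr, samples, _ = small_cohort
    return build_dataset(expr, samples, SYMPTOM)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
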