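import warnings

import pytest

from m6apat.io_preprocess import correct_batches
from m6apat.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest multi-batch cohort with every kind of planted structure."""
    cfg = SimulationConfig(
        n_cases=90,
        n_controls=60,
        n_genes=900,
        n_lncrnas=60,
        n_batches=3,
        immune_set_size=10,
        noise_sd=1.0,
        seed=42,
    )
    expr, annotation, truth = simulate_cohort(cfg)
    return cfg, expr, annotation, truth


@pytest.fixture(scope="session")
def corrected_cohort(small_cohort):
    cfg, expr, annotation, truth = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = correct_batches(expr, annotation)
    return cfg, corrected, annotation, truth
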