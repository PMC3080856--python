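"""Shared fixtures: one small simulated experiment reused across modules."""

import pytest

from rdnakit import expression_model as em
from rdnakit import synthetic_data as sd

SEED = 20260


@pytest.fixture(scope="session")
def annotation():
    return sd.generate_annotation(2000, seed=SEED)


@pytest.fixture(scope="session")
def truth(annotation):
    return sd.generate_truth(annotation, frac_sensitive=0.10, seed=SEED + 1)


@pytest.fixture(scope="session")
def design():
    return sd.dye_balanced_design(["mild1", "mild2", "gross"], n_reps=6)


@pytest.fixture(scope="session")
def spots(annotation, truth, design):
    return sd.simulate_arrays(
        annotation, truth, design, noise_sd=0.2, qc_dropout=0.02, seed=SEED + 2
    )


@pytest.fixture(scope="session")
def matrix(spots):
    return em.loess_normalize(spots)


@pytest.fixture(scope="session")
def gross_results(matrix, design):
    return em.run_contrast(matrix, design, ("gross", "wildtype"))


@pytest.fixture(scope="session")
def mild_results(matrix, design):
    return em.run_contrast(matrix, design, ("mild2", "wildtype"))
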