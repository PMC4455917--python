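"""Shared fixtures: small synthetic studies sized for fast unit tests."""

import pandas as pd
import pytest

from mechsig.model import stack_strengths
from mechsig.pipeline import cohorts_to_strengths
from mechsig.simulate import SimulationConfig, simulate_study

SMALL_CONFIG = SimulationConfig(
    cohort_sizes=(24, 16),
    nr_fraction=0.3,
    n_genes=300,
    platform_retention=0.9,
    n_mechanisms=40,
    mechanism_size_range=(4, 15),
    n_informative=4,
    effect_size=0.8,
    gene_noise_sd=1.0,
)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SMALL_CONFIG, seed=20240901)


@pytest.fixture(scope="session")
def small_strengths(small_study):
    strengths, kept = cohorts_to_strengths(
        small_study["cohorts"], small_study["kb"], min_genes=4
    )
    return strengths, kept


@pytest.fixture(scope="session")
def small_design(small_study, small_strengths):
    """(X, labels, cohorts) stacked over the small study's cohorts."""
    strengths, _ = small_strengths
    X, cohorts = stack_strengths(strengths)
    labels = small_study["labels"].loc[X.index]
    return X, labels, cohorts
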