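import numpy as np
import pytest

from ushrv.pipeline import analyze_population
from ushrv.synth import default_population_spec, generate_population

# Fixed study seeds for the default cohort used across the suite.
GENERATOR_SEED = 42
SEGMENTATION_SEED = 7
AGREEMENT_SEED = 11
NULLSIM_SEED = 13


@pytest.fixture(scope="session")
def default_population():
    """The default synthetic cohort: 500 subjects, fixed seed."""
    spec = default_population_spec(n_subjects=500, seed=GENERATOR_SEED)
    return generate_population(spec)


@pytest.fixture(scope="session")
def default_run(default_population):
    """Full agreement analysis of the default cohort."""
    return analyze_population(default_population,
                              segmentation_seed=SEGMENTATION_SEED,
                              bootstrap_seed=AGREEMENT_SEED)


@pytest.fixture(scope="session")
def small_population():
    """A 30-subject cohort for cheap pipeline-level tests."""
    spec = default_population_spec(n_subjects=30, seed=GENERATOR_SEED + 1)
    return generate_population(spec)
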