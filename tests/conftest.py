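import numpy as np
import pandas as pd
import pytest

from feedcast import DietSpec
from feedcast.synthetic import GeneratorSpec, TruthSpec, generate


@pytest.fixture(scope="session")
def diet():
    return DietSpec()


@pytest.fixture(scope="session")
def heifer_cohort_10k():
    """Large single-sex cohort with default marginals for calibration checks."""
    return generate(GeneratorSpec(n_heifers=10_000, n_steers=0), seed=11)


@pytest.fixture(scope="session")
def eq9_truth_cohort():
    """Mixed-sex cohort of n=1499 with the AFSBW_CT generating truth active."""
    spec = GeneratorSpec(
        n_heifers=673, n_steers=826, truth=TruthSpec("eq9", target_total_sd=65.7)
    )
    return generate(spec, seed=7)


@pytest.fixture()
def small_cohort():
    """Small mixed cohort for pipeline-level tests."""
    return generate(GeneratorSpec(n_heifers=60, n_steers=80), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
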