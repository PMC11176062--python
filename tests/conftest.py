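import numpy as np
import pandas as pd
import pytest

import mivoom as mv


@pytest.fixture(scope="session")
def complete_cohort():
    """Complete (no missingness) cohort of 300 samples."""
    complete, _ = mv.simulate_cohort(300, missing=False, seed=11)
    return complete


@pytest.fixture(scope="session")
def masked_cohort():
    """Cohort of 300 samples with standard missingness rates."""
    _, masked = mv.simulate_cohort(300, seed=11)
    return masked


@pytest.fixture(scope="session")
def small_counts(complete_cohort):
    counts, truth = mv.simulate_counts(complete_cohort, n_genes=400, seed=12)
    return counts, truth


@pytest.fixture(scope="session")
def sle_spec():
    return mv.DesignSpec(exposure="sle_sum")


@pytest.fixture(scope="session")
def de_result(small_counts, complete_cohort, sle_spec):
    counts, _ = small_counts
    return mv.run_de(counts, complete_cohort, sle_spec)
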