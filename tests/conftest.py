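import warnings

import numpy as np
import pytest

from tgxpod import synth

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def study_design():
    return synth.StudyDesign(seed=11)


@pytest.fixture(scope="session")
def small_expression_study(study_design):
    """200-gene study with 25% responsive genes, shared across tests."""
    matrix, truth = synth.simulate_expression_study(
        study_design, n_genes=200, responsive_fraction=0.25)
    return matrix, truth


@pytest.fixture(scope="session")
def small_deg_table(small_expression_study):
    matrix, _ = small_expression_study
    return synth.make_deg_table(matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(2718)
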