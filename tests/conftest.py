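import numpy as np
import pytest

from psychoscreen import normalize, screen_features_vs_panel
from psychoscreen.config import RunConfig
from psychoscreen.synthetic import CohortConfig, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (8 subjects x 13 timepoints, 200 taxa,
    5 planted), shared across tests that only read it."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_screen(default_cohort):
    """The default cohort screened at default thresholds."""
    taxa, panel, _meta, _truth = default_cohort
    return screen_features_vs_panel(normalize(taxa), panel, RunConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (80 taxa, 3 planted) for tests that must re-screen."""
    return generate_cohort(CohortConfig(seed=3, n_taxa=80, n_planted=3))
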