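import numpy as np
import pytest
from hypothesis import settings

from hdacnet import GenePanel, default_cohort_spec, simulate_cohort, subset_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """n=200 cohort with 3 planted and 8 null RTKs (session-cached)."""
    spec = default_cohort_spec(n_samples=200, n_planted=3, n_null_rtks=8, noise_sd=0.5, seed=7)
    expr, truth = simulate_cohort(spec)
    return expr, truth


@pytest.fixture(scope="session")
def small_cohort_blocks(small_cohort):
    expr, truth = small_cohort
    panel = truth.panel()
    hdac_block, rtk_block, _ = subset_panel(expr, panel)
    return hdac_block, rtk_block, panel, truth


@pytest.fixture
def default_panel():
    return GenePanel(rtk_genes=("NTRK1", "FGFR3", "KIT"))
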