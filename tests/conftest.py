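import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from panelpost.panel import Amplicon, PanelDefinition
from panelpost.simulate import SimulationConfig, demo_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel() -> PanelDefinition:
    return demo_panel()


@pytest.fixture(scope="session")
def default_cohort(panel):
    """One default cohort, shared read-only across tests."""
    return simulate_cohort(SimulationConfig(seed=7), panel)


@pytest.fixture(scope="session")
def many_cohorts(panel):
    """100 seeded default cohorts for replicate-level properties."""
    return [simulate_cohort(SimulationConfig(seed=s), panel) for s in range(100)]


@pytest.fixture
def toy_amplicon() -> Amplicon:
    return Amplicon(
        name="TOY_amp1", chrom="chrT", start=100, end=250,
        fwd_primer_len=25, rev_primer_len=25, gene="TOY",
    )
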