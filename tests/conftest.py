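import warnings

import pytest

from hybridaction import SimConfig, simulate_panel

# statsmodels emits convergence warnings on deliberately tiny fixtures
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_panel():
    """Cheap panel for plumbing tests (not powered for recovery checks)."""
    return simulate_panel(SimConfig(n_genes=300, n_inbreds=20, n_trios=10,
                                    cluster_genes=15, seed=2))


@pytest.fixture(scope="session")
def midi_panel():
    """Panel with enough accessions/trios for statistical recovery."""
    return simulate_panel(SimConfig(n_genes=800, n_inbreds=50, n_trios=30,
                                    cluster_genes=30, seed=7))


@pytest.fixture(scope="session")
def panel_dir(tmp_path_factory, small_panel):
    from hybridaction.io import write_panel
    out = tmp_path_factory.mktemp("panel")
    return write_panel(small_panel, str(out))
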