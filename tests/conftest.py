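import numpy as np
import pytest

from circmotif.pipeline import RunConfig, run_pipeline
from circmotif.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default study conditions: 10,000 genes, 8% motif carriers, seed 1."""
    out = tmp_path_factory.mktemp("default_ds")
    return generate_dataset(SyntheticConfig(seed=1), out)


@pytest.fixture(scope="session")
def default_report(default_dataset):
    """One full pipeline run on the default dataset, shared across tests."""
    return run_pipeline(RunConfig.from_dataset(default_dataset))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A reduced dataset for fast structural tests (signal still planted)."""
    out = tmp_path_factory.mktemp("small_ds")
    cfg = SyntheticConfig(n_genes=1500, n_decoy_peaks=150, seed=7)
    return generate_dataset(cfg, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
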