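import numpy as np
import pytest

from alphafoci.pipeline import RunConfig, run_pipeline


@pytest.fixture()
def rng():
    return np.random.default_rng(20220823)


@pytest.fixture(scope="session")
def small_pipeline():
    """Four-dose pipeline run at modest size, shared across tests."""
    cfg = RunConfig(doses_gy=(0.05, 0.2, 0.5, 1.0), n_nuclei=350,
                    master_seed=42)
    return run_pipeline(cfg)
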