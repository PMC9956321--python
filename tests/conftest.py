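import numpy as np
import pytest

from outlierboot import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down two-group dataset with planted outliers."""
    cfg = SimConfig(
        n_transcripts=300,
        samples_per_group=30,
        outliers_per_group=3,
        n_de_transcripts=30,
        n_outlier_de_transcripts=15,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
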