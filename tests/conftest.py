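import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ecoresp.core_io import OguCountTable, SampleMetadata
from ecoresp.simulate import SimConfig, simulate_cohorts


@pytest.fixture
def small_table() -> OguCountTable:
    values = np.array(
        [
            [2.0, 0.0, 5.0],
            [0.0, 3.0, 1.0],
            [1.0, 1.0, 0.0],
            [4.0, 2.0, 2.0],
        ]
    )
    return OguCountTable(["s1", "s2", "s3", "s4"], ["o1", "o2", "o3"], values)


@pytest.fixture
def small_meta() -> dict[str, SampleMetadata]:
    return {
        "s1": SampleMetadata("s1", "dsA", "R"),
        "s2": SampleMetadata("s2", "dsA", "NR"),
        "s3": SampleMetadata("s3", "dsB", "R", cancer_type="other"),
        "s4": SampleMetadata("s4", "dsB", "NR", cancer_type="other"),
    }


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated collection shared across tests."""
    cfg = SimConfig(
        seed=11,
        n_datasets=3,
        samples_per_dataset=40,
        n_ogus=80,
        target_sparsity=0.4,
        prevalence_shape=(2.0, 2.0),
        baseline_log_sd=1.0,
        noise_log_sd=0.3,
        dataset_cancer=("melanoma", "melanoma", "other"),
    )
    return simulate_cohorts(cfg)
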