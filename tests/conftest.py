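import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ptrseq import synthetic_data as sd

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> sd.SimulationConfig:
    """Compact study conditions for unit tests: short regions, few genes."""
    defaults = dict(
        n_genes=120, n_tissues=3, n_replicates=2, cds_codons_mean=120,
        utr3_length_log_mean=float(np.log(300.0)), seed=11,
    )
    defaults.update(overrides)
    return sd.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset() -> sd.SimulatedDataset:
    return sd.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def records(small_dataset) -> list:
    return small_dataset.transcripts
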