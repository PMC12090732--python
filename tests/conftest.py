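import numpy as np
import pandas as pd
import pytest

from symbiocor.dataio import CountMatrix, SampleTable
from symbiocor.synthgen import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One desk-scale dataset under the full study-emulating defaults."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def null_config():
    """Generator configuration with every planted structure switched off."""
    return SynthConfig(
        n_latent=0,
        n_de_genes=0,
        mixed_shift_sd_symA=0.0,
        mixed_shift_sd_symB=0.0,
        seed=17,
    )


@pytest.fixture(scope="session")
def null_dataset(null_config):
    return generate_dataset(null_config)


@pytest.fixture
def tiny_counts():
    """A 3-gene x 4-sample count matrix with easy hand arithmetic."""
    df = pd.DataFrame(
        [[10, 0, 5, 1], [20, 5, 5, 2], [30, 5, 10, 1]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CountMatrix("host", df)


@pytest.fixture
def tiny_meta():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "culture": ["5L", "5L", "5LN", "5LN"],
                "status": ["singleA", "singleA", "mixed", "mixed"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


def status_series(meta: SampleTable) -> pd.Series:
    return meta.table.set_index("sample_id")["status"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
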