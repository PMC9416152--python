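import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabotu.containers import MetaboliteMatrix, OtuCountTable, SampleMetadata
from metabotu.simulate import SimulationConfig, generate_dataset

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-scale coupled dataset with the default 10/18/13 sample split."""
    cfg = SimulationConfig(n_otus=40, n_metabolites=30, n_driver_metabolites=3,
                           n_target_otus=4, seed=11)
    return generate_dataset(cfg)


@pytest.fixture
def tiny_meta():
    frame = pd.DataFrame(
        {
            "treatment": ["D-W"] * 4 + ["W-D"] * 4 + ["Sat"] * 4,
            "core": ["c1", "c1", "c2", "c2", "c3", "c3", "c4", "c4", "c5", "c5", "c6", "c6"],
            "replicate": [1, 2] * 6,
        },
        index=[f"s{i:02d}" for i in range(12)],
    )
    frame.index.name = "sample_id"
    return SampleMetadata(frame)


@pytest.fixture
def tiny_counts(tiny_meta):
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 50, size=(12, 8))
    counts[rng.random((12, 8)) < 0.4] = 0
    counts[:, 0] = 1  # everywhere-present OTU
    return OtuCountTable(
        pd.DataFrame(counts, index=tiny_meta.sample_ids,
                     columns=[f"otu{j}" for j in range(8)])
    )


@pytest.fixture
def tiny_metab(tiny_meta):
    rng = np.random.default_rng(7)
    values = np.exp2(rng.normal(8, 1, size=(12, 6)))
    values[rng.random((12, 6)) < 0.15] = np.nan
    return MetaboliteMatrix(
        pd.DataFrame(values, index=tiny_meta.sample_ids,
                     columns=[f"met{j}" for j in range(6)])
    )
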