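import numpy as np
import pandas as pd
import pytest

from tmtbridge import SimConfig, normalize_pipeline, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated dataset (2000 proteins, 5% dropout, seed 11)."""
    cfg = SimConfig(seed=11)
    matrices, design, truth = simulate_dataset(cfg)
    return cfg, matrices, design, truth


@pytest.fixture(scope="session")
def default_norm(default_sim):
    cfg, matrices, design, truth = default_sim
    norm, report = normalize_pipeline(matrices, design)
    return norm, report


@pytest.fixture(scope="session")
def clean_sim():
    """Nuisance-free dataset: no noise, no loading, no batch effect, no dropout."""
    cfg = SimConfig(
        n_proteins=300, noise_sd_log2=0.0, channel_loading_sd_log2=0.0,
        batch_effect_sd_log2=0.0, dropout_rate=0.0, seed=5,
    )
    matrices, design, truth = simulate_dataset(cfg)
    return cfg, matrices, design, truth


@pytest.fixture
def tiny_matrix():
    """2x3 matrix with column sums (10, 20, 30)."""
    from tmtbridge import IntensityMatrix

    data = pd.DataFrame(
        [[4.0, 16.0, 9.0], [6.0, 4.0, 21.0]],
        index=pd.Index(["P1", "P2"], name="protein"),
        columns=["c1", "c2", "c3"],
    )
    return IntensityMatrix("B1", data)
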