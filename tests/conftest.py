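import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fracmod import (
    FitOptions,
    NormalizationSet,
    SampleDesign,
    fit,
    simulate_dataset,
)
from fracmod.simulate import SimConfig

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def single_replicate_design():
    """One sample per fraction, the minimal identifiable layout."""
    return SampleDesign(
        pd.DataFrame(
            {
                "fraction": ["input", "eluate", "supernatant"],
                "replicate": ["1", "1", "1"],
                "condition": ["c", "c", "c"],
            },
            index=pd.Index(["i1", "e1", "s1"], name="sample"),
        )
    )


@pytest.fixture(scope="session")
def unit_norm(single_replicate_design):
    return NormalizationSet(
        depth={s: 1.0 for s in single_replicate_design.sample_ids},
        fraction_scale={"input": 1.0, "eluate": 1.0, "supernatant": 1.0},
    )


@pytest.fixture(scope="session")
def recovery_dataset():
    """500 genes, 2 replicates per fraction, theta=100: the parameter-recovery
    simulation shared by the heavier tests."""
    cfg = SimConfig(n_genes=500, n_replicates=2, theta=100.0, seed=2024)
    counts, design, truth = simulate_dataset(cfg)
    return counts, design, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_dataset):
    counts, design, truth = recovery_dataset
    return fit(counts, design, FitOptions()), truth


@pytest.fixture(scope="session")
def spikein_dataset():
    """Low-noise dataset with post-IP spike-ins for cross-method comparisons."""
    cfg = SimConfig(
        n_genes=300,
        n_replicates=1,
        theta=10000.0,
        seed=77,
        mu_count_low=2000.0,
        mu_count_high=50000.0,
        n_spikeins=50,
        x_eluate=1.4,
        x_supernatant=0.9,
    )
    counts, design, truth = simulate_dataset(cfg)
    spike_ids = list(truth.spike_abundance.index)
    return counts, design, truth, spike_ids
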