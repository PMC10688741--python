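"""Shared fixtures: tiny simulated datasets and fast training configs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from toxtransfer import (
    ArchitectureSpec,
    SimulationDesign,
    TrainingConfig,
    build_learning_examples,
    normalize_dataset,
    simulate_dataset,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_design() -> SimulationDesign:
    """3 compounds x 5 genes with a moderate shift; cheap to train on."""
    return SimulationDesign(
        n_compounds=3,
        gene_count=5,
        noise_sd=0.01,
        domain_shift_magnitude=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_design):
    ds, truth = simulate_dataset(tiny_design)
    return ds, truth


@pytest.fixture(scope="session")
def tiny_examples(tiny_data):
    ds, _ = tiny_data
    norm = normalize_dataset(ds, fit_scope=ds.compounds)
    source, target = build_learning_examples(norm)
    return norm, source, target


@pytest.fixture(scope="session")
def toy_arch(tiny_design) -> ArchitectureSpec:
    """Small trunk + arm matching the 5-gene fixture (input 15, output 20)."""
    g = tiny_design.gene_count
    return ArchitectureSpec(
        input_dim=3 * g,
        output_dim=4 * g,
        hidden_sizes=(12, 9, 6, 10, 14),
        latent_layer_index=2,
        domain_arm_sizes=(4,),
    )


@pytest.fixture()
def fast_config() -> TrainingConfig:
    return TrainingConfig(epochs=5, batch_size=16, seed=3)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
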