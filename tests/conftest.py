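from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ergpanel import RunConfig, SimulationConfig, simulate_experiment
from ergpanel.io import ExpressionExperiment

#: Seed shipped with the package's worked examples and stochastic checks.
PACKAGED_SEED = 20220817


@pytest.fixture(scope="session")
def packaged_seed() -> int:
    return PACKAGED_SEED


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Scaled-down study conditions: 2,000 genes, 6 replicate pairs,
    5% stable-up / 5% stable-down / 5% unstable responders."""
    return SimulationConfig(n_genes=2000, n_replicates=6, frac_up=0.05,
                            frac_down=0.05, frac_unstable=0.05,
                            seed=PACKAGED_SEED)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    return simulate_experiment(sim_config)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    """Selection config matched to the scaled-down simulation: panels the
    size of the planted responder classes."""
    return RunConfig(n_up=100, n_down=100, top_k=30, seed=PACKAGED_SEED)


@pytest.fixture
def toy_experiment() -> ExpressionExperiment:
    """Three genes x two replicates with hand-checkable values."""
    genes = ("GENE_A", "GENE_B", "GENE_C")
    treated = np.array([[8.0, 8.0], [1.0, 1.0], [2.0, 4.0]])
    control = np.array([[2.0, 2.0], [4.0, 4.0], [2.0, 4.0]])
    return ExpressionExperiment(gene_ids=genes, treated=treated,
                                control=control,
                                replicate_labels=("r1", "r2"))


def make_experiment(treated, control, genes=None) -> ExpressionExperiment:
    treated = np.atleast_2d(np.asarray(treated, float))
    control = np.atleast_2d(np.asarray(control, float))
    if genes is None:
        genes = tuple(f"G{i}" for i in range(1, treated.shape[0] + 1))
    labels = tuple(f"r{i}" for i in range(1, treated.shape[1] + 1))
    return ExpressionExperiment(gene_ids=tuple(genes), treated=treated,
                                control=control, replicate_labels=labels)
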