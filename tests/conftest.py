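"""Shared fixtures: synthetic geometry bundles and cached experiment runs.

Session-scoped because anatomy construction and grid runs are the costly
parts; all fixtures are deterministic functions of fixed seeds.
"""

import numpy as np
import pytest

from hippomeg import experiments as exp

MASTER_SEED = 1


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small anatomy (800 + 100 vertices, 100 sensors) for unit tests."""
    return exp.build_anatomy("tiny", seed=7)


@pytest.fixture(scope="session")
def desk_bundle():
    """Desk-scale anatomy (2000 + 162 vertices, 274 sensors)."""
    return exp.build_anatomy("desk",
                             seed=exp.derive_seed(MASTER_SEED, "anatomy"))


@pytest.fixture(scope="session")
def headline_results(desk_bundle):
    """The headline cell: 30 hippocampal + 30 cortical simulations at
    SNR -5 dB, zero co-registration error, inverted with MNE, EBB and MSP
    under both anatomical models."""
    cfg = exp.ExperimentConfig(schemes=("MNE", "EBB", "MSP"),
                               structures=("hippocampal", "cortical"),
                               n_sims_per_cell=30, master_seed=MASTER_SEED)
    return exp.run_grid(cfg, bundle=desk_bundle)


@pytest.fixture(scope="session")
def mixture_results(desk_bundle):
    """Four-dipole mixture experiment at reduced repetitions."""
    cfg = exp.ExperimentConfig(n_sims_per_cell=12, master_seed=MASTER_SEED)
    return exp.run_mixture_experiment(cfg, bundle=desk_bundle)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
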