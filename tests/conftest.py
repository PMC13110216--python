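import numpy as np
import pytest

from trnkit.simdata import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """Small planted simulation shared across read-only tests."""
    cfg = SimConfig(
        n_tfs=4,
        targets_per_tf=10,
        n_nontarget_genes=20,
        reps_per_condition=6,
        seed=42,
    )
    counts, annotation, truth = simulate_counts(cfg)
    return cfg, counts, annotation, truth


@pytest.fixture(scope="session")
def strong_sim():
    """Strong-coupling simulation used for recovery tests."""
    cfg = SimConfig(
        n_tfs=10,
        targets_per_tf=30,
        n_nontarget_genes=40,
        reps_per_condition=10,
        seed=12,
    )
    counts, annotation, truth = simulate_counts(cfg)
    return cfg, counts, annotation, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
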