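import numpy as np
import pytest

from clanprof.synthetic_data import EvalueModel, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def vertical_dataset():
    """30 noise-free families, no lateral transfer, 20 exact replicates."""
    cfg = SimConfig(
        seed=11,
        n_families=30,
        p_lgt=0.0,
        n_bootstrap=20,
        bootstrap_perturb=0.0,
        evalue_model=EvalueModel(noise_sd=0.0),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def lgt_dataset():
    """Noise-free families in which every family with a partner lineage
    received one planted transfer into a focal leaf."""
    cfg = SimConfig(
        seed=12,
        n_families=40,
        p_lgt=1.0,
        n_bootstrap=0,
        bootstrap_perturb=0.0,
        evalue_model=EvalueModel(noise_sd=0.0),
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
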