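import pytest

from eqtmkit import ChainSpec, SimConfig, pair_cis, run_model, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One moderately sized simulated study shared across tests."""
    cfg = SimConfig(
        n_cpgs=300,
        n_genes=40,
        n_samples=150,
        chains=ChainSpec(n_chains=8, n_null_snps=6),
    )
    return simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def small_pairs(small_sim):
    return pair_cis(small_sim.cpgs, small_sim.genes)


@pytest.fixture(scope="session")
def small_assoc(small_sim, small_pairs):
    return run_model(small_pairs, small_sim.meth, small_sim.expr, small_sim.covars)
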