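import numpy as np
import pytest

from qstscan import prep, quantgen
from qstscan.sim import SimConfig, make_sample_table, simulate_expression


@pytest.fixture(scope="session")
def design_samples():
    """The full 32-genotype, 2-nitrogen, 2-replicate sample sheet."""
    return make_sample_table(SimConfig(n_genes=1, seed=0))


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated expression dataset (30 genes)."""
    cfg = SimConfig(n_genes=30, seed=7)
    counts, samples, truth = simulate_expression(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def h2_recovery_fit():
    """200-gene simulation with V_S=1, V_G=1, V_e=0.25 (analytic H2 = 16/17)
    plus its fitted variance components; shared by recovery tests."""
    cfg = SimConfig(
        n_genes=200, v_s=1.0, v_g=1.0, v_n=0.0, v_sxn=0.0, v_gxn=0.0,
        v_e=0.25, phi=0.0, mu0=float(np.log(500.0)), seed=1,
    )
    counts, samples, truth = simulate_expression(cfg)
    norm = prep.normalize(counts)
    varcomp = quantgen.fit_variance_components(norm, samples)
    return cfg, norm, samples, truth, varcomp
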