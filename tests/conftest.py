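import numpy as np
import pytest
from hypothesis import settings

from trilayer import SimConfig, simulate_study

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def default_study():
    """One default-config simulated study shared across read-only tests."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def module_network_config():
    """The 4-module planted network condition: 200 genes, within-module
    latent correlation 0.8, between-module 0.1, two trait-coupled modules."""
    def make(seed: int) -> SimConfig:
        return SimConfig(
            n_ppms=50,
            n_boms=49,
            n_hc=1,
            n_genes=200,
            planted_modules=[
                (list(range(i * 50, (i + 1) * 50)), 0.8, "PPMS" if i < 2 else None)
                for i in range(4)
            ],
            module_between_rho=0.1,
            meqtl_targets=[],
            meth_to_expr=[],
            seed=seed,
        )
    return make


@pytest.fixture(scope="session")
def dmr_config():
    """The planted-DMR condition: delta-beta over 8 consecutive probes at
    n = 60 cases / 60 controls among 500 background probes."""
    def make(seed: int, delta: float = 0.24) -> SimConfig:
        return SimConfig(
            n_ppms=60,
            n_boms=60,
            n_hc=1,
            n_snps=12,
            ld_blocks=[(6, 0.95), (6, 0.9)],
            meqtl_targets=[],
            meth_to_expr=[],
            planted_modules=[],
            n_genes=5,
            dmr_spec=((100, 108), delta),
            risk_snps=[],
            seed=seed,
        )
    return make


def pytest_configure(config):
    np.seterr(all="ignore")
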