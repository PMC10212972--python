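import dataclasses

import numpy as np
import pytest

from cteqtl import GeneSnpData, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def null_gene():
    """One scenario-1 gene with no eQTL (eta = 1 everywhere), n = 150."""
    return simulate_dataset(SimConfig(scenario=1, n=150, seed=42))


@pytest.fixture(scope="session")
def eqtl_gene():
    """One scenario-1 gene with a strong CT1 eQTL (eta = (2, 1, 1))."""
    return simulate_dataset(SimConfig(scenario=1, n=300,
                                      eta=(2.0, 1.0, 1.0), seed=7))


@pytest.fixture(scope="session")
def small_gene():
    """A 50-sample single-cell-type (Q = 1) fixture for oracle checks."""
    rng = np.random.default_rng(11)
    n = 50
    X = rng.normal(size=(n, 2))
    Z = rng.choice(4, size=n, p=[0.36, 0.24, 0.24, 0.16])
    cfg = SimConfig(scenario=1, n=n, Q=1, kappa=(1.0,), eta=(1.8,),
                    phi=0.08, psi=0.04, beta=(0.3, -0.2), seed=99)
    from cteqtl import simulate_counts

    rho = np.ones((n, 1))
    T, N, N2 = simulate_counts(cfg, rho, X, Z, seed=13)
    return GeneSnpData(T=T, N=N, N2=N2, Z=Z, X=X, rho=rho)


def perturb(data, **kw):
    return dataclasses.replace(data, **kw)
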