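"""Synthetic data generation for the cell type-specific eQTL simulation study.

Three cell type-proportion scenarios are supported for Q = 3 cell types:

1. i.i.d. softmax of U(-4, 4) draws — equally abundant, highly variable.
2. rho_1 ~ Beta(10, 24); rho_2 = |0.85 - 0.76 rho_1 - 0.03 rho_1^2 + eps|
   with eps ~ N(0, 0.02^2); rho_3 = 1 - rho_1 - rho_2, clamped at 0 and
   renormalized — a realistic composition where the third cell type is
   rare and has little variance.
3. Scenario 2 plus outliers: per cell type, values above the 99% quantile
   are replaced by U(0.7, 0.9) draws and values below the 1% quantile by
   U(0, 0.1) draws, then rows are renormalized.

Counts are generated from the same mean structure the model fits: TReC is
negative binomial with the mixture mean, the total ASReC is a fixed
fraction of the TReC, and the haplotype-2 ASReC is beta-binomial with the
genotype-dependent success probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import AA, AB, BA, BB, CSeQTLParams, GeneSnpData, compute_mu, compute_xi

DEFAULT_BETA = (0.5, 0.2, -0.2, 0.1)


@dataclass
class SimConfig:
    """Study conditions for one simulated gene-SNP pair.

    Defaults follow the simulation design: n = 300 samples, Q = 3 cell
    types, reference-allele mean TReC of 500 in cell type 1, ASReC equal
    to 5% of TReC, and minor allele frequency 0.2.  Mild overdispersion
    (phi = 0.1, psi = 0.05) is the default count noise.
    """

    scenario: int = 1
    n: int = 300
    Q: int = 3
    mu_A1: float = 500.0
    kappa: tuple = (1.0, 1.0, 1.0)
    eta: tuple = (1.0, 1.0, 1.0)
    phi: float = 0.1
    psi: float = 0.05
    maf: float = 0.2
    ase_fraction: float = 0.05
    beta: tuple = DEFAULT_BETA
    binomial_thinning: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if not (0 < self.ase_fraction < 1):
            raise ValueError("ase_fraction must be in (0, 1)")
        if self.phi < 0 or self.psi < 0:
            raise ValueError("phi and psi must be >= 0")
        kappa = np.asarray(self.kappa, dtype=float)
        if kappa.shape != (self.Q,) or not np.isclose(kappa[0], 1.0):
            raise ValueError("kappa must have length Q with kappa[0] = 1")
        if np.any(kappa < 0) or np.any(np.asarray(self.eta) <= 0):
            raise ValueError("kappa >= 0 and eta > 0 required")

    def params(self) -> CSeQTLParams:
        return CSeQTLParams(
            mu_A1=self.mu_A1,
            beta=np.asarray(self.beta, dtype=float),
            phi=self.phi,
            kappa=np.asarray(self.kappa, dtype=float),
            eta=np.asarray(self.eta, dtype=float),
            psi=self.psi,
            reference=0,
        )


def simulate_proportions(scenario: int, n: int, Q: int = 3,
                         seed=None) -> np.ndarray:
    """Simulate an n x Q row-stochastic cell type proportion matrix."""
    if scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if scenario == 1:
        u = rng.uniform(-4.0, 4.0, size=(n, Q))
        e = np.exp(u)
        return e / e.sum(axis=1, keepdims=True)
    if Q != 3:
        raise ValueError("scenarios 2 and 3 are defined for Q = 3")
    rho1 = rng.beta(10.0, 24.0, size=n)
    eps = rng.normal(0.0, 0.02, size=n)
    rho2 = np.abs(0.85 - 0.76 * rho1 - 0.03 * rho1 ** 2 + eps)
    rho3 = 1.0 - rho1 - rho2
    rho3 = np.where(rho3 < 0, 0.0, rho3)
    rho = np.column_stack([rho1, rho2, rho3])
    rho = rho / rho.sum(axis=1, keepdims=True)
    if scenario == 2:
        return rho
    # scenario 3: tail replacement per cell type, then renormalize
    for q in range(Q):
        col = rho[:, q]
        lo, hi = np.quantile(col, [0.01, 0.99])
        high = col > hi
        low = col < lo
        col[high] = rng.uniform(0.7, 0.9, size=high.sum())
        col[low] = rng.uniform(0.0, 0.1, size=low.sum())
    return rho / rho.sum(axis=1, keepdims=True)


def simulate_covariates(n: int, seed=None, standardize: bool = True):
    """Simulate the four baseline covariates.

    Column 1 is read depth ~ Gamma(shape 600, rate 100); column 2 is a
    Bernoulli(0.5) indicator; columns 3 and 4 are U(-1, 1) and N(0, 1).
    Continuous columns are centered and scaled to unit variance when
    ``standardize`` is set.  Returns (X, raw_read_depth).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    depth = rng.gamma(shape=600.0, scale=1.0 / 100.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    x3 = rng.uniform(-1.0, 1.0, size=n)
    x4 = rng.normal(0.0, 1.0, size=n)
    X = np.column_stack([depth, sex, x3, x4])
    if standardize:
        for j in (0, 2, 3):
            X[:, j] = (X[:, j] - X[:, j].mean()) / X[:, j].std()
    return X, depth


def simulate_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """Phased genotypes under Hardy-Weinberg equilibrium.

    Categorical draw over (AA, AB, BA, BB) with probabilities
    ((1-m)^2, m(1-m), m(1-m), m^2) where m is the minor (B) allele
    frequency."""
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    m = maf
    probs = np.array([(1 - m) ** 2, m * (1 - m), m * (1 - m), m ** 2])
    return rng.choice(np.array([AA, AB, BA, BB]), size=n, p=probs)


def simulate_counts(config: SimConfig, rho: np.ndarray, X: np.ndarray,
                    Z: np.ndarray, seed=None):
    """Simulate (T, N, N2) given proportions, covariates and genotypes.

    TReC ~ NB(mu_i, phi) with the mixture mean; N = round(f * T) with the
    ASReC fraction f (binomial thinning optional); the B-haplotype ASReC is
    beta-binomial with pi from the genotype case, and N2 is recovered from
    the haplotype orientation.
    """
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.asarray(Z, dtype=int)
    n = rho.shape[0]
    if X.shape[0] != n or Z.shape[0] != n:
        raise ValueError("rho, X and Z must have matching sample counts")
    rng = np.random.default_rng(seed)
    params = config.params()
    mu = compute_mu(params, rho, X, Z)
    if config.phi > 0:
        r = 1.0 / config.phi
        lam = rng.gamma(shape=r, scale=mu / r)
        T = rng.poisson(lam)
    else:
        T = rng.poisson(mu)
    if config.binomial_thinning:
        N = rng.binomial(T, config.ase_fraction)
    else:
        N = np.round(config.ase_fraction * T).astype(int)
    # success probability for the B-haplotype read count
    xi_a = compute_xi(rho, params.kappa, params.eta)
    pi = np.where((Z == AB) | (Z == BA), xi_a / (1.0 + xi_a), 0.5)
    if config.psi > 0:
        a = pi / config.psi
        b = (1.0 - pi) / config.psi
        pdraw = rng.beta(a, b)
        yB = rng.binomial(N, pdraw)
    else:
        yB = rng.binomial(N, pi)
    # N2 counts haplotype 2: the B haplotype for AB, the A haplotype for BA;
    # homozygote draws (pi = 0.5) are symmetric either way
    N2 = np.where(Z == BA, N - yB, yB)
    return T.astype(int), N.astype(int), N2.astype(int)


def simulate_dataset(config: SimConfig) -> GeneSnpData:
    """Simulate one complete gene-SNP dataset from a single seed.

    Independent sub-streams are derived for proportions, covariates,
    genotypes and counts so each component is individually reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    s_rho, s_cov, s_geno, s_cnt = root.spawn(4)
    rho = simulate_proportions(config.scenario, config.n, config.Q, s_rho)
    X, _ = simulate_covariates(config.n, s_cov)
    Z = simulate_genotypes(config.n, config.maf, s_geno)
    T, N, N2 = simulate_counts(config, rho, X, Z, s_cnt)
    return GeneSnpData(T=T, N=N, N2=N2, Z=Z, X=X, rho=rho)
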