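"""Joint likelihood for cell type-specific eQTL mapping from bulk RNA-seq.

Per gene-SNP pair, the total read count (TReC) ``T_i`` follows a negative
binomial distribution whose mean mixes cell type-specific allelic means
through the sample's cell type proportions, and the haplotype-2
allele-specific read count (ASReC) ``N_i2`` follows a beta-binomial
distribution whose success probability is driven by the same cell
type-specific eQTL effect sizes.  The two likelihood factors share the
nuisance fold changes ``kappa_q`` (reference-allele expression of cell type
q relative to the reference cell type) and, under the cis model, the eQTL
fold changes ``eta_q`` (B-allele vs A-allele expression in cell type q).

The bulk eQTL effect for sample i is the proportion-weighted mixture

    xi_i = sum_q rho_iq * eta_q * kappa_q / sum_q rho_iq * kappa_q

and the expected TReC is

    mu_i = mu_AA_i            for genotype AA
         = mu_AA_i (1+xi)/2   for AB or BA
         = mu_AA_i * xi       for BB

with log(mu_AA_i) = log(2 mu_A1) + X_i' beta + log(sum_q rho_iq kappa_q).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.special import gammaln, betaln

# phased genotype codes; haplotype 1 carries the first-listed allele
AA, AB, BA, BB = 0, 1, 2, 3
GENOTYPE_LABELS = {"AA": AA, "AB": AB, "BA": BA, "BB": BB}

Mode = Literal["trec", "cis", "cistrans"]
MODES = ("trec", "cis", "cistrans")


class DegenerateMixtureError(ValueError):
    """All expressed cell types have zero proportion for some sample."""


@dataclass
class GeneSnpData:
    """Observed data for one gene-SNP pair.

    T : total read counts, length n, non-negative integers.
    N, N2 : total and haplotype-2 allele-specific read counts, 0 <= N2 <= N.
    Z : phased genotype codes in {AA, AB, BA, BB} (0..3).
    X : n x p covariate matrix (no intercept column).
    rho : n x Q cell type proportions, rows summing to 1.
    """

    T: np.ndarray
    N: np.ndarray
    N2: np.ndarray
    Z: np.ndarray
    X: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        self.N2 = np.asarray(self.N2, dtype=float)
        self.Z = np.asarray(self.Z, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        n = self.T.shape[0]
        for name in ("N", "N2", "Z"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length != length of T")
        if self.X.shape[0] != n or self.rho.shape[0] != n:
            raise ValueError("X / rho row count != length of T")
        if np.any(self.T < 0) or np.any(self.T != np.round(self.T)):
            raise ValueError("T must contain non-negative integers")
        if np.any(self.N2 > self.N) or np.any(self.N2 < 0):
            raise ValueError("require 0 <= N2 <= N")
        if not np.allclose(self.rho.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rho rows must sum to 1")
        if not np.isin(self.Z, [AA, AB, BA, BB]).all():
            raise ValueError("Z codes must be in {0,1,2,3}")

    @property
    def n(self) -> int:
        return self.T.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def Q(self) -> int:
        return self.rho.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        """Number of B alleles: 0 for AA, 1 for AB/BA, 2 for BB."""
        return np.select([self.Z == AA, self.Z == BB], [0, 2], default=1)


@dataclass
class CSeQTLParams:
    """Full parameter vector for the joint model.

    mu_A1 : expected reference-allele TReC in the reference cell type.
    beta : covariate effects (shared across cell types).
    phi : NB overdispersion, Var[T] = mu + phi mu^2; 0 selects Poisson.
    kappa : Q-vector of reference-allele fold changes, kappa[ref] = 1;
        an entry of exactly 0 marks a non-expressed cell type.
    eta : Q-vector of eQTL fold changes (TReC scale).
    psi : beta-binomial overdispersion; 0 selects binomial.
    alpha : Q-vector of cis/trans ratios, eta_ASE_q = eta_q * alpha_q.
    """

    mu_A1: float
    beta: np.ndarray
    phi: float = 0.0
    kappa: np.ndarray = None
    eta: np.ndarray = None
    psi: float = 0.0
    alpha: np.ndarray = None
    reference: int = 0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.kappa is None:
            self.kappa = np.ones(1)
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        Q = self.kappa.shape[0]
        if self.eta is None:
            self.eta = np.ones(Q)
        if self.alpha is None:
            self.alpha = np.ones(Q)
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if not np.isclose(self.kappa[self.reference], 1.0):
            raise ValueError("kappa at the reference cell type must be 1")
        if self.mu_A1 <= 0 or self.phi < 0 or self.psi < 0:
            raise ValueError("mu_A1 > 0 and phi, psi >= 0 required")
        if np.any(self.kappa < 0) or np.any(self.eta <= 0) or np.any(self.alpha <= 0):
            raise ValueError("kappa >= 0; eta, alpha > 0 required")

    @property
    def Q(self) -> int:
        return self.kappa.shape[0]

    def eta_ase(self) -> np.ndarray:
        return self.eta * self.alpha

    def copy(self) -> "CSeQTLParams":
        return replace(
            self,
            beta=self.beta.copy(),
            kappa=self.kappa.copy(),
            eta=self.eta.copy(),
            alpha=self.alpha.copy(),
        )


def compute_xi(rho: np.ndarray, kappa: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Bulk eQTL effect size per sample.

    xi_i = sum_q rho_iq eta_q kappa_q / sum_q rho_iq kappa_q.  Collapses to
    the common value of eta when the eQTL effect is shared by all cell types.
    """
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    denom = rho @ kappa
    if np.any(denom <= 0):
        raise DegenerateMixtureError(
            "zero mixture mean: every expressed cell type has rho = 0 for "
            f"sample(s) {np.nonzero(denom <= 0)[0].tolist()}"
        )
    return (rho @ (eta * kappa)) / denom


def compute_mu(
    params: CSeQTLParams,
    rho: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    eta: np.ndarray | None = None,
) -> np.ndarray:
    """Expected TReC per sample under the mixture mean structure.

    ``eta`` overrides the TReC-scale eQTL effects (used to evaluate the mean
    with the ASE-scale effects where needed); defaults to ``params.eta``.
    """
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.asarray(Z, dtype=int)
    if eta is None:
        eta = params.eta
    S = rho @ params.kappa
    if np.any(S <= 0):
        raise DegenerateMixtureError(
            "zero mixture mean for sample(s) "
            f"{np.nonzero(S <= 0)[0].tolist()}"
        )
    log_mu_AA = np.log(2.0 * params.mu_A1) + X @ params.beta + np.log(S)
    xi = (rho @ (eta * params.kappa)) / S
    het = (Z == AB) | (Z == BA)
    log_mu = log_mu_AA.copy()
    log_mu[het] += np.log1p(xi[het]) - np.log(2.0)
    hom_b = Z == BB
    log_mu[hom_b] += np.log(xi[hom_b])
    return np.exp(log_mu)


def nb_loglik(T: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Negative binomial log-likelihood, NB2 parameterization.

    Var[T] = mu + phi mu^2; phi = 0 evaluates the Poisson limit exactly.
    """
    T = np.asarray(T, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(T < 0) or np.any(T != np.round(T)):
        raise ValueError("T must contain non-negative integers")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    # below ~1e-8 the NB terms lose all precision in double arithmetic and
    # the Poisson limit is exact to O(phi)
    if phi < 1e-8:
        return float(np.sum(T * np.log(mu) - mu - gammaln(T + 1.0)))
    r = 1.0 / phi
    ll = (
        gammaln(T + r)
        - gammaln(r)
        - gammaln(T + 1.0)
        + r * (np.log(r) - np.log(r + mu))
        + T * (np.log(mu) - np.log(r + mu))
    )
    return float(np.sum(ll))


def _bb_logpmf(y: np.ndarray, n: np.ndarray, pi: np.ndarray, psi: float) -> np.ndarray:
    """Beta-binomial log pmf with mean n*pi and overdispersion psi.

    Standard shapes are a = pi/psi, b = (1-pi)/psi so psi -> 0 recovers the
    binomial; psi = 0 is an explicit binomial branch.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    pi = np.broadcast_to(np.asarray(pi, dtype=float), y.shape)
    binom = gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)
    if psi == 0.0:
        return binom + y * np.log(pi) + (n - y) * np.log1p(-pi)
    a = pi / psi
    b = (1.0 - pi) / psi
    return binom + betaln(y + a, n - y + b) - betaln(a, b)


def bb_loglik(
    N2: np.ndarray,
    N: np.ndarray,
    Z: np.ndarray,
    xi_A: np.ndarray,
    psi: float,
) -> float:
    """ASReC log-likelihood over the four phased-genotype cases.

    Samples with N = 0 contribute 0.  Heterozygotes model the B-haplotype
    read count with pi = xi_A/(1+xi_A): for AB that count is N2, for BA it
    is N - N2.  Homozygotes use pi = 0.5 and inform only the
    overdispersion psi.
    """
    N2 = np.asarray(N2, dtype=float)
    N = np.asarray(N, dtype=float)
    Z = np.asarray(Z, dtype=int)
    xi_A = np.broadcast_to(np.asarray(xi_A, dtype=float), N.shape)
    if np.any(N2 > N) or np.any(N2 < 0):
        raise ValueError("require 0 <= N2 <= N")
    obs = N > 0
    if not np.any(obs):
        return 0.0
    pi = np.full(N.shape, 0.5)
    het = (Z == AB) | (Z == BA)
    pi[het] = xi_A[het] / (1.0 + xi_A[het])
    # B-haplotype count: haplotype 2 for AB, haplotype 1 (= N - N2) for BA
    y = np.where(Z == BA, N - N2, N2)
    return float(np.sum(_bb_logpmf(y[obs], N[obs], pi[obs], psi)))


def joint_loglik(data: GeneSnpData, params: CSeQTLParams, mode: Mode = "cis") -> float:
    """Joint log-likelihood of TReC and ASReC.

    mode "trec" uses the NB factor only; "cis" ties the ASE eQTL effects to
    the TReC effects (alpha = 1); "cistrans" uses eta_ASE_q = eta_q alpha_q
    in the beta-binomial factor.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    mu = compute_mu(params, data.rho, data.X, data.Z)
    ll = nb_loglik(data.T, mu, params.phi)
    if mode == "trec":
        return ll
    eta_a = params.eta if mode == "cis" else params.eta_ase()
    xi_a = compute_xi(data.rho, params.kappa, eta_a)
    return ll + bb_loglik(data.N2, data.N, data.Z, xi_a, params.psi)
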