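"""Likelihood-core checks: mixture effect sizes, NB/BB factors, identities."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import betabinom, binom, nbinom, poisson

from cteqtl import (
    AA,
    AB,
    BA,
    BB,
    CSeQTLParams,
    GeneSnpData,
    bb_loglik,
    compute_mu,
    compute_xi,
    joint_loglik,
    nb_loglik,
)
from cteqtl.models import DegenerateMixtureError


class TestXi:
    def test_hand_computed_mixture(self):
        xi = compute_xi(np.array([0.5, 0.3, 0.2]), np.array([1, 2, 0.5]),
                        np.array([2.0, 1.0, 1.0]))
        assert xi[0] == pytest.approx(1.7 / 1.2, abs=1e-12)

    @pytest.mark.parametrize("c", [0.3, 1.0, 2.5])
    def test_common_effect_collapses_to_bulk(self, c):
        rng = np.random.default_rng(0)
        rho = rng.dirichlet(np.ones(4), size=6)
        kappa = rng.uniform(0.1, 5, size=4)
        xi = compute_xi(rho, kappa, np.full(4, c))
        assert np.allclose(xi, c, atol=1e-12)

    def test_degenerate_mixture_raises(self):
        with pytest.raises(DegenerateMixtureError):
            compute_xi(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                       np.ones(2))

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 500))
    def test_invariant_to_kappa_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        rho = rng.dirichlet(np.ones(3), size=5)
        kappa = rng.uniform(0.2, 4, size=3)
        eta = rng.uniform(0.5, 2, size=3)
        assert np.allclose(compute_xi(rho, kappa, eta),
                           compute_xi(rho, kappa * scale, eta), rtol=1e-10)


class TestMu:
    def _params(self, **kw):
        defaults = dict(mu_A1=500.0, beta=np.zeros(1),
                        kappa=np.ones(3), eta=np.ones(3))
        defaults.update(kw)
        return CSeQTLParams(**defaults)

    def test_aa_reference_mean_is_two_mu(self):
        # with all fold changes 1 and centered covariates the AA mean is
        # twice the per-allele mean
        mu = compute_mu(self._params(), np.full((1, 3), 1 / 3),
                        np.zeros((1, 1)), np.array([AA]))
        assert mu[0] == pytest.approx(1000.0, abs=1e-9)

    def test_null_eqtl_heterozygote_equals_aa(self):
        mu = compute_mu(self._params(), np.full((1, 3), 1 / 3),
                        np.zeros((1, 1)), np.array([AB]))
        assert mu[0] == pytest.approx(1000.0, abs=1e-9)

    def test_bb_mean_composes_offset_and_xi(self):
        p = self._params(kappa=np.array([1, 2, 0.5]),
                         eta=np.array([2.0, 1.0, 1.0]))
        mu = compute_mu(p, np.array([[0.5, 0.3, 0.2]]), np.zeros((1, 1)),
                        np.array([BB]))
        # 2*500*1.2 * (1.7/1.2)
        assert mu[0] == pytest.approx(1700.0, abs=1e-8)

    def test_two_celltype_mean_matches_direct_formula(self):
        # Q=2: mu_i = exp(X b) * [rho1 (mu_{z,1}) + rho2 (mu_{z,2})] written
        # out per genotype without the xi factorization
        rng = np.random.default_rng(3)
        rho = rng.dirichlet(np.ones(2), size=20)
        X = rng.normal(size=(20, 2))
        Z = rng.choice(4, size=20)
        mu_A = np.array([40.0, 90.0])
        eta = np.array([1.7, 0.6])
        p = CSeQTLParams(mu_A1=mu_A[0], beta=np.array([0.3, -0.2]),
                         kappa=mu_A / mu_A[0], eta=eta)
        mu = compute_mu(p, rho, X, Z)
        mu_B = mu_A * eta
        per_ct = {AA: 2 * mu_A, AB: mu_A + mu_B, BA: mu_A + mu_B,
                  BB: 2 * mu_B}
        direct = np.array([
            np.exp(X[i] @ p.beta) * rho[i] @ per_ct[Z[i]]
            for i in range(20)
        ])
        assert np.allclose(mu, direct, rtol=1e-10)


class TestNB:
    def test_poisson_limit_value(self):
        assert nb_loglik(np.array([3]), np.array([3.0]), 0.0) == \
            pytest.approx(poisson.logpmf(3, 3), abs=1e-10)

    def test_continuity_at_phi_zero(self):
        T = np.array([0, 2, 7, 15])
        mu = np.array([1.0, 3.0, 6.0, 14.0])
        assert nb_loglik(T, mu, 0.0) == pytest.approx(
            nb_loglik(T, mu, 1e-12), abs=1e-6)

    def test_matches_scipy_nbinom(self):
        T = np.arange(6)
        mu = np.linspace(1, 11, 6)
        phi = 0.3
        r = 1 / phi
        expected = nbinom.logpmf(T, r, r / (r + mu)).sum()
        assert nb_loglik(T, mu, phi) == pytest.approx(expected, rel=1e-10)

    def test_sum_decomposes_over_samples(self):
        T = np.array([1, 4, 9])
        mu = np.array([2.0, 3.0, 8.0])
        total = nb_loglik(T, mu, 0.2)
        parts = sum(nb_loglik(T[i:i + 1], mu[i:i + 1], 0.2)
                    for i in range(3))
        assert total == pytest.approx(parts, abs=1e-10)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            nb_loglik(np.array([-1]), np.array([1.0]), 0.1)


class TestBB:
    def test_zero_ase_contributes_nothing(self):
        assert bb_loglik(np.array([0]), np.array([0]), np.array([AB]),
                         np.array([2.0]), 0.1) == 0.0

    def test_homozygote_binomial_half(self):
        got = bb_loglik(np.array([5]), np.array([10]), np.array([AA]),
                        np.array([1.0]), 0.0)
        assert got == pytest.approx(binom.logpmf(5, 10, 0.5), abs=1e-10)

    def test_matches_scipy_betabinom(self):
        xi = 1.8
        pi = xi / (1 + xi)
        psi = 0.07
        got = bb_loglik(np.array([4]), np.array([12]), np.array([AB]),
                        np.array([xi]), psi)
        expected = betabinom.logpmf(4, 12, pi / psi, (1 - pi) / psi)
        assert got == pytest.approx(expected, rel=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(n=st.integers(1, 40), frac=st.floats(0, 1), xi=st.floats(0.2, 5),
           psi=st.floats(0, 0.5))
    def test_haplotype_labeling_symmetry(self, n, frac, xi, psi):
        # AB with N2 successes == BA with N - N2 successes
        n2 = int(round(frac * n))
        ab = bb_loglik(np.array([n2]), np.array([n]), np.array([AB]),
                       np.array([xi]), psi)
        ba = bb_loglik(np.array([n - n2]), np.array([n]), np.array([BA]),
                       np.array([xi]), psi)
        assert ab == pytest.approx(ba, rel=1e-12)

    def test_rejects_n2_above_n(self):
        with pytest.raises(ValueError):
            bb_loglik(np.array([3]), np.array([2]), np.array([AA]),
                      np.array([1.0]), 0.0)


class TestJoint:
    def _params(self, Q=3):
        return CSeQTLParams(mu_A1=100.0,
                            beta=np.array([0.2, -0.1, 0.05, 0.3]), phi=0.1,
                            kappa=np.linspace(1, 2, Q) / 1.0,
                            eta=np.linspace(0.8, 1.5, Q), psi=0.05,
                            alpha=np.ones(Q))

    def test_no_ase_collapses_to_trec(self, null_gene):
        data = dataclasses.replace(null_gene,
                                   N=np.zeros(null_gene.n),
                                   N2=np.zeros(null_gene.n))
        p = self._params()
        p.kappa[0] = 1.0
        assert joint_loglik(data, p, "joint_cis" if False else "cis") == \
            pytest.approx(joint_loglik(data, p, "trec"), abs=1e-10)

    def test_unit_alpha_ties_cistrans_to_cis(self, null_gene):
        p = self._params()
        assert joint_loglik(null_gene, p, "cistrans") == \
            pytest.approx(joint_loglik(null_gene, p, "cis"), abs=1e-10)

    def test_single_celltype_matches_bulk_trecase_oracle(self, small_gene):
        """Q = 1 joint likelihood equals an independently coded bulk
        TReC+ASE likelihood built from scipy distributions."""
        d = small_gene
        mu_A1, beta, phi, eta, psi = 55.0, np.array([0.25, -0.1]), 0.09, \
            1.6, 0.03
        p = CSeQTLParams(mu_A1=mu_A1, beta=beta, phi=phi,
                         kappa=np.ones(1), eta=np.array([eta]), psi=psi)
        got = joint_loglik(d, p, "cis")

        # oracle: direct bulk model
        mu_AA = 2 * mu_A1 * np.exp(d.X @ beta)
        geno_factor = {AA: 1.0, AB: (1 + eta) / 2, BA: (1 + eta) / 2,
                       BB: eta}
        mu = mu_AA * np.array([geno_factor[z] for z in d.Z])
        r = 1 / phi
        ll = nbinom.logpmf(d.T.astype(int), r, r / (r + mu)).sum()
        pi_het = eta / (1 + eta)
        for i in range(d.n):
            if d.N[i] == 0:
                continue
            if d.Z[i] == AB:
                y, pi = d.N2[i], pi_het
            elif d.Z[i] == BA:
                y, pi = d.N[i] - d.N2[i], pi_het
            else:
                y, pi = d.N2[i], 0.5
            ll += betabinom.logpmf(int(y), int(d.N[i]), pi / psi,
                                   (1 - pi) / psi)
        assert got == pytest.approx(ll, abs=1e-8)

    @settings(max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 100))
    def test_celltype_label_permutation_invariance(self, seed, null_gene):
        """Permuting cell type labels (with matching rho, kappa, eta, alpha
        columns) leaves the likelihood unchanged."""
        rng = np.random.default_rng(seed)
        perm = rng.permutation(3)
        p = self._params()
        d2 = dataclasses.replace(null_gene, rho=null_gene.rho[:, perm])
        # re-reference kappa so kappa[new reference] = 1
        kappa_p = p.kappa[perm]
        p2 = CSeQTLParams(mu_A1=p.mu_A1 * kappa_p[0], beta=p.beta,
                          phi=p.phi, kappa=kappa_p / kappa_p[0],
                          eta=p.eta[perm], psi=p.psi, alpha=p.alpha[perm])
        for mode in ("trec", "cis", "cistrans"):
            assert joint_loglik(null_gene, p, mode) == pytest.approx(
                joint_loglik(d2, p2, mode), rel=1e-10)

    def test_invalid_mode_rejected(self, null_gene):
        with pytest.raises(ValueError):
            joint_loglik(null_gene, self._params(), "bulk")
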