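"""Staged-optimizer checks: stage logic, convergence verdicts,
identifiability rules and reference swapping."""

import dataclasses

import numpy as np
import pytest

from cteqtl import (
    CSeQTLParams,
    GeneSnpData,
    NonExpressedGeneError,
    SimConfig,
    check_convergence,
    fit_gene,
    fit_stage,
    joint_loglik,
    simulate_dataset,
    swap_reference,
)
from cteqtl.models import AA


class TestStages:
    def test_stage1_poisson_closed_form(self):
        # intercept-only, all-AA genotypes: the Poisson MLE of the AA mean
        # is the sample mean, so mu_A1 = mean(T) / 2
        rng = np.random.default_rng(0)
        n = 120
        T = rng.poisson(800.0, size=n)
        data = GeneSnpData(T=T, N=np.zeros(n), N2=np.zeros(n),
                           Z=np.full(n, AA), X=np.zeros((n, 1)),
                           rho=np.full((n, 3), 1 / 3))
        start = CSeQTLParams(mu_A1=100.0, beta=np.zeros(1),
                             kappa=np.ones(3))
        params, ll, *_ = fit_stage(data, start, 1, use_phi=False,
                                   use_psi=False)
        assert params.mu_A1 == pytest.approx(T.mean() / 2, rel=1e-8)

    def test_poisson_data_selects_poisson(self):
        # simulated with phi = 0: the boundary test should usually drop the
        # NB overdispersion
        hits = 0
        for s in range(8):
            d = simulate_dataset(SimConfig(n=200, phi=0.0, psi=0.0,
                                           seed=400 + s))
            fit = fit_gene(d, mode="trec")
            hits += not fit.use_phi
        assert hits >= 6

    def test_overdispersed_data_keeps_nb(self):
        d = simulate_dataset(SimConfig(n=300, phi=0.3, seed=9))
        fit = fit_gene(d, mode="trec")
        assert fit.use_phi
        assert fit.params.phi == pytest.approx(0.3, rel=0.4)

    def test_stage_warm_start_never_decreases_loglik(self, null_gene):
        lls = []
        params = CSeQTLParams(mu_A1=float(null_gene.T.mean()) / 2,
                              beta=np.zeros(null_gene.p),
                              kappa=np.ones(3))
        prev = None
        for stage, use_phi in ((1, False), (2, True), (3, True), (4, True)):
            if stage == 2:
                params = params.copy()
                params.phi = 1.0
            params, ll, *_ = fit_stage(null_gene, params, stage,
                                       mode="trec", use_phi=use_phi,
                                       use_psi=False)
            if prev is not None:
                assert ll >= prev - 1e-6
            prev = ll
            lls.append(ll)


class TestConvergence:
    def test_zero_gradient_positive_definite(self):
        ok, gn, sn, why = check_convergence(np.zeros(3), np.eye(3))
        assert ok and gn == 0 and sn == 0

    def test_singular_information_not_converged(self):
        H = np.diag([1.0, 1.0, 0.0])
        ok, *_rest, why = check_convergence(np.zeros(3), H)
        assert not ok and why == "non-invertible"

    def test_large_gradient_not_converged(self):
        ok, gn, _sn, _ = check_convergence(np.full(3, 1e-2), np.eye(3),
                                           eps1=1e-3)
        assert not ok and gn > 1e-3

    def test_negative_variance_not_converged(self):
        H = np.diag([1.0, -1.0])
        ok, *_ , why = check_convergence(np.zeros(2), H)
        assert not ok and why == "negative variance"


class TestReferenceSwap:
    def _params(self):
        return CSeQTLParams(mu_A1=100.0, beta=np.array([0.1]),
                            phi=0.05, kappa=np.array([1.0, 5.0, 0.2]),
                            eta=np.array([1.5, 0.8, 1.0]), psi=0.02)

    def test_ratio_definitions(self):
        out = swap_reference(self._params(), 1)
        assert out.mu_A1 == pytest.approx(500.0)
        assert np.allclose(out.kappa, [0.2, 1.0, 0.04])
        assert np.allclose(out.eta, self._params().eta)  # eta is unchanged

    def test_involution(self):
        p = self._params()
        back = swap_reference(swap_reference(p, 2), 0)
        assert back.mu_A1 == pytest.approx(p.mu_A1, rel=1e-12)
        assert np.allclose(back.kappa, p.kappa, rtol=1e-12)

    def test_likelihood_invariance(self, null_gene):
        p = self._params()
        p.beta = np.zeros(null_gene.p)
        for new_ref in (1, 2):
            q = swap_reference(p, new_ref)
            assert joint_loglik(null_gene, q, "cis") == pytest.approx(
                joint_loglik(null_gene, p, "cis"), abs=1e-8)

    def test_cannot_swap_to_zeroed(self):
        p = self._params()
        p.kappa[2] = 0.0
        with pytest.raises(ValueError):
            swap_reference(p, 2)


class TestIdentifiability:
    def test_silent_celltype_gets_zeroed(self):
        # CT3 reference-allele expression 1e-4-fold of CT1: its mean TReC
        # is far below one read per haplotype
        d = simulate_dataset(SimConfig(n=200, kappa=(1.0, 1.0, 1e-4),
                                       seed=21))
        fit = fit_gene(d, mode="cis")
        assert fit.ledger.kappa_zeroed[2]
        assert fit.ledger.eta_fixed[2]
        assert fit.params.kappa[2] == 0.0
        assert fit.params.eta[2] == 1.0
        assert fit.converged

    def test_identifiable_gene_has_empty_ledger(self, eqtl_gene):
        fit = fit_gene(eqtl_gene, mode="cis")
        assert fit.converged
        assert not fit.ledger.kappa_zeroed.any()
        assert not fit.ledger.eta_fixed.any()

    def test_all_zero_counts_is_non_expressed(self, null_gene):
        n = null_gene.n
        dead = dataclasses.replace(null_gene, T=np.zeros(n),
                                   N=np.zeros(n), N2=np.zeros(n))
        with pytest.raises(NonExpressedGeneError):
            fit_gene(dead, mode="cis")

    def test_result_converged_or_explained(self):
        # every fit either passes the convergence verdict or carries a
        # non-empty constraint ledger / failure message
        for s in range(5):
            d = simulate_dataset(SimConfig(scenario=2, n=120,
                                           seed=900 + s))
            fit = fit_gene(d, mode="cis")
            assert fit.converged or fit.ledger.reasons or fit.message


class TestRecovery:
    def test_joint_fit_recovers_parameters(self, eqtl_gene):
        fit = fit_gene(eqtl_gene, mode="cis")
        assert fit.converged
        # truth: mu_A1=500, kappa=1, eta=(2,1,1), phi=0.1, psi=0.05
        assert fit.params.eta[0] == pytest.approx(2.0, rel=0.25)
        assert fit.params.phi == pytest.approx(0.1, rel=0.5)
        out_ref = fit.ledger.output_reference
        assert fit.params.reference == out_ref
        assert fit.params.kappa[out_ref] == 1.0

    def test_common_eta_constrained_fit_recovers_bulk_effect(self):
        # counts simulated with a shared eQTL effect follow the bulk model;
        # fixing eta_2 = eta_3 = 1 and a common-effect fit is emulated by a
        # Q=1 collapse of the same data
        cfg = SimConfig(n=300, Q=1, kappa=(1.0,), eta=(1.6,),
                        beta=(0.3, -0.2), seed=31)
        rng = np.random.default_rng(17)
        X = rng.normal(size=(300, 2))
        Z = rng.choice(4, size=300, p=[0.64, 0.16, 0.16, 0.04])
        from cteqtl import simulate_counts

        T, N, N2 = simulate_counts(cfg, np.ones((300, 1)), X, Z, seed=32)
        d = GeneSnpData(T=T, N=N, N2=N2, Z=Z, X=X, rho=np.ones((300, 1)))
        fit = fit_gene(d, mode="cis")
        assert fit.params.eta[0] == pytest.approx(1.6, rel=0.15)
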