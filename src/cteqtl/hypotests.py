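"""Per-cell-type eQTL tests, cis/trans tests, permutation p-values and FDR.

The headline test for cell type q is a likelihood-ratio test of
H0: eta_q = 1 against H0: eta_q != 1, using either the TReC-only model
(trans-eQTL) or the joint TReC+ASReC model (cis-eQTL).  The cis/trans test
compares eta_ASE_q to eta_q through H0: alpha_q = 1.  Gene-level
significance is assessed by permuting genotype vectors across samples and
recomputing the minimum p-value over the gene's local SNPs; eGenes are
called by Storey q-values on the permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2

from .fitting import FitResult, fit_gene
from .models import GeneSnpData, Mode


class OptimizerFailure(RuntimeError):
    """The constrained fit beat the full fit beyond numerical tolerance."""


@dataclass
class CellTypeTest:
    stat: float
    df: int
    p: float
    testable: bool = True
    note: str = ""


@dataclass
class TestResult:
    """Test output for one gene-SNP pair."""

    eqtl: list  # CellTypeTest per cell type
    cistrans: list = None
    full_fit: FitResult = None


_LL_SLACK = 1e-4  # constrained fit may exceed full fit by optimizer noise


def _lrt(ll_full: float, ll_null: float, df: int = 1):
    stat = 2.0 * (ll_full - ll_null)
    if stat < -_LL_SLACK:
        raise OptimizerFailure(
            f"constrained log-likelihood exceeds the full one by {-stat/2:.3g}"
        )
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df=df))


def test_eqtl_celltype(
    data: GeneSnpData,
    q: int,
    mode: Mode = "cis",
    full_fit: FitResult | None = None,
) -> CellTypeTest:
    """LRT of eta_q = 1 for one cell type.

    mode "trec" tests the TReC model (trans-eQTL); "cis" tests the joint
    model with shared TReC/ASE effects.  Cell types whose eta was pinned
    by the identifiability rules are reported untestable with p = 1.
    """
    if full_fit is None:
        full_fit = fit_gene(data, mode=mode)
    if full_fit.ledger.eta_fixed[q] or full_fit.ledger.kappa_zeroed[q]:
        return CellTypeTest(stat=0.0, df=1, p=1.0, testable=False,
                            note="eta pinned by identifiability rules")
    null_fit = fit_gene(data, mode=mode, fix_eta=(q,),
                        init_params=full_fit.params,
                        use_phi=full_fit.use_phi, use_psi=full_fit.use_psi,
                        base_ledger=full_fit.ledger)
    stat, p = _lrt(full_fit.loglik, null_fit.loglik)
    return CellTypeTest(stat=stat, df=1, p=p)


def test_cistrans(
    data: GeneSnpData,
    q: int,
    full_fit: FitResult | None = None,
) -> CellTypeTest:
    """LRT of alpha_q = 1 (cis vs trans) for one cell type.

    All information about alpha comes from the allele-specific counts, so
    a gene with no ASReC is untestable."""
    if np.all(data.N == 0):
        return CellTypeTest(stat=0.0, df=1, p=1.0, testable=False,
                            note="no allele-specific reads")
    if full_fit is None:
        full_fit = fit_gene(data, mode="cistrans")
    if full_fit.ledger.alpha_fixed[q]:
        return CellTypeTest(stat=0.0, df=1, p=1.0, testable=False,
                            note="alpha pinned by identifiability rules")
    null_fit = fit_gene(data, mode="cistrans", fix_alpha=(q,),
                        init_params=full_fit.params,
                        use_phi=full_fit.use_phi, use_psi=full_fit.use_psi,
                        base_ledger=full_fit.ledger)
    stat, p = _lrt(full_fit.loglik, null_fit.loglik)
    return CellTypeTest(stat=stat, df=1, p=p)


def snp_min_p(data_per_snp: list, mode: Mode = "cis",
              cell_types: list | None = None) -> float:
    """Minimum eQTL p-value over SNPs and cell types for one gene."""
    best = 1.0
    for data in data_per_snp:
        fit = fit_gene(data, mode=mode)
        Q = data.Q
        for q in (cell_types if cell_types is not None else range(Q)):
            t = test_eqtl_celltype(data, q, mode=mode, full_fit=fit)
            if t.testable:
                best = min(best, t.p)
    return best


def gene_permutation_p(
    gene_data: list,
    B: int = 1000,
    mode: Mode = "cis",
    seed=None,
    cell_types: list | None = None,
):
    """Gene-level permutation p-value for the minimum p over local SNPs.

    ``gene_data`` holds one GeneSnpData per local SNP (shared T, N, N2, X,
    rho; distinct Z).  Each permutation applies one shared sample
    permutation to every SNP's genotype vector, leaving everything else
    fixed.  Returns (perm_p, observed_min_p).
    """
    if not gene_data:
        raise ValueError("no SNPs in the gene window")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    observed = snp_min_p(gene_data, mode=mode, cell_types=cell_types)
    n = gene_data[0].n
    hits = 0
    for _b in range(B):
        idx = rng.permutation(n)
        permuted = [replace(d, Z=d.Z[idx]) for d in gene_data]
        if snp_min_p(permuted, mode=mode, cell_types=cell_types) <= observed:
            hits += 1
    return (1.0 + hits) / (B + 1.0), observed


def storey_qvalues(pvals: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda.

    pi0 = min(1, mean(p > lambda) / (1 - lambda)); with fewer than 10
    p-values pi0 is fixed at 1 (Benjamini-Hochberg)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[0]
    if m >= 10:
        pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
        pi0 = max(pi0, 1.0 / m)  # guard: all p below lambda
    else:
        pi0 = 1.0
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p[i] / rank)
        q[i] = val
        prev = val
    return q


def qvalue_select(perm_pvals: np.ndarray, q_cutoff: float = 0.005,
                  lam: float = 0.5):
    """Call eGenes: q-value below the cutoff.  Returns (flags, qvalues)."""
    q = storey_qvalues(perm_pvals, lam=lam)
    return q < q_cutoff, q
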