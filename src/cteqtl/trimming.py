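"""Influence-based trimming of total read counts.

A sample's influence on a gene is measured by a Cook's distance computed
from the genotype-free TReC model (the null model: covariates and cell
type proportions, no SNP):

    C_i = (1/m) sum_j (mu_j(i) - mu_j)^2 / v_j,   m = p + Q - 1

where mu_j(i) is the fitted mean for sample j after excluding sample i and
v_j = mu_j + phi mu_j^2.  Because the mixture offset makes the model
non-standard, leverage cannot be read off a hat matrix; leave-one-out
refits are approximated by a one-step Newton update from the full fit
(exact refits are available for validation).  Cook's distances are put on
a common scale across genes by centering at the median and scaling by the
raw median absolute deviation; samples whose normalized distance exceeds a
threshold c have their TReC replaced by the null-model prediction.  The
threshold is calibrated by running genotype-permuted TReC-only eQTL scans
and keeping the largest candidate that controls type I error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .fitting import (
    fit_null_trec,
    fit_stage,
    observed_information,
)
from .hypotests import test_eqtl_celltype
from .models import GeneSnpData


@dataclass
class TrimResult:
    cooks: np.ndarray
    normalized: np.ndarray
    trimmed_index: np.ndarray
    imputed: np.ndarray
    threshold: float
    data: GeneSnpData


def _per_sample_score(x, data, spec):
    """Per-sample score contributions for the genotype-free TReC model."""
    from scipy.special import digamma

    params = spec.unpack(x)
    kappa = params.kappa
    S = data.rho @ kappa
    mu = np.exp(np.log(2.0 * params.mu_A1) + data.X @ params.beta + np.log(S))
    T = data.T
    cols = []
    if spec.use_phi and params.phi > 0:
        r = 1.0 / params.phi
        w = T - mu * (T + r) / (mu + r)
        dldr = (
            digamma(T + r) - digamma(r) + np.log(r) + 1.0
            - np.log(r + mu) - (r + T) / (r + mu)
        )
        lphi_col = -r * dldr
    else:
        w = T - mu
        lphi_col = None
    cols.append(w)
    for j in range(data.p):
        cols.append(w * data.X[:, j])
    if lphi_col is not None:
        cols.append(lphi_col)
    for q in spec.free_kappa:
        cols.append(w * data.rho[:, q] * kappa[q] / S)
    return np.column_stack(cols)


def _null_mu(params, data):
    S = data.rho @ params.kappa
    return np.exp(np.log(2.0 * params.mu_A1) + data.X @ params.beta + np.log(S))


def cooks_distance(data: GeneSnpData, exact_loo: bool = False):
    """Cook's distance per sample from the genotype-free TReC null model.

    Returns (C, null_params).  ``exact_loo`` replaces the one-step Newton
    leave-one-out update with a full refit per left-out sample."""
    params, spec, x, _ll, ledger, use_phi = fit_null_trec(data)
    m = data.p + data.Q - 1
    if data.n <= m:
        raise ValueError("n <= p + Q - 1: leave-one-out is unstable")
    mu_hat = _null_mu(params, data)
    v_hat = mu_hat + params.phi * mu_hat ** 2
    C = np.zeros(data.n)
    if exact_loo:
        for i in range(data.n):
            keep = np.ones(data.n, dtype=bool)
            keep[i] = False
            sub = GeneSnpData(
                T=data.T[keep], N=data.N[keep], N2=data.N2[keep],
                Z=data.Z[keep], X=data.X[keep], rho=data.rho[keep],
            )
            sub_ledger = ledger.copy()
            p_i, _, _, _, _ = fit_stage(
                sub, params.copy(), 3, mode="trec", ledger=sub_ledger,
                use_phi=use_phi, use_psi=False,
            )
            mu_loo = _null_mu(p_i, data)
            C[i] = np.sum((mu_loo - mu_hat) ** 2 / v_hat) / m
    else:
        H = observed_information(x, data, spec)
        Hinv = np.linalg.inv(H)
        scores = _per_sample_score(x, data, spec)
        # one-step Newton update after dropping sample i:
        # theta_(i) ~= theta_hat - H^{-1} g_i
        for i in range(data.n):
            x_i = x - Hinv @ scores[i]
            p_i = spec.unpack(x_i)
            mu_loo = _null_mu(p_i, data)
            C[i] = np.sum((mu_loo - mu_hat) ** 2 / v_hat) / m
    return C, params


def normalize_cooks(C: np.ndarray) -> np.ndarray:
    """Median/MAD normalization: (C - med(C)) / mad(C), raw MAD."""
    C = np.asarray(C, dtype=float)
    if C.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    med = np.median(C)
    mad = np.median(np.abs(C - med))
    if mad == 0:
        warnings.warn("MAD of Cook's distances is zero; no trimming possible")
        return np.zeros_like(C)
    return (C - med) / mad


def trim_and_impute(data: GeneSnpData, c: float,
                    exact_loo: bool = False) -> TrimResult:
    """Trim samples with normalized Cook's distance above c.

    Trimmed samples have their TReC replaced by the null-model predicted
    mean, rounded to the nearest non-negative integer; allele-specific
    counts are untouched."""
    if c <= 0:
        raise ValueError("threshold c must be positive")
    C, null_params = cooks_distance(data, exact_loo=exact_loo)
    Cn = normalize_cooks(C)
    flag = Cn > c
    # impute, then refit the null model on the imputed data and re-impute
    # until the replacement values stabilise: the first null fit is still
    # contaminated by the outliers it flags
    mu0 = _null_mu(null_params, data)
    imputed = np.maximum(np.round(mu0), 0.0)
    new_data = replace(data, T=np.where(flag, imputed, data.T))
    if np.any(flag):
        for _ in range(5):
            params, *_rest = fit_null_trec(new_data)
            refreshed = np.maximum(np.round(_null_mu(params, new_data)), 0.0)
            if np.array_equal(refreshed[flag], imputed[flag]):
                break
            imputed = refreshed
            new_data = replace(data, T=np.where(flag, imputed, data.T))
    return TrimResult(
        cooks=C, normalized=Cn, trimmed_index=np.nonzero(flag)[0],
        imputed=imputed[flag], threshold=c, data=new_data,
    )


def calibrate_threshold(
    datasets: list,
    candidate_thresholds=(40.0, 20.0, 10.0, 5.0),
    alpha: float = 0.05,
    seed=None,
    mode: str = "trec",
):
    """Select the largest trimming threshold that controls type I error.

    For every gene dataset the genotype vector is permuted (breaking any
    true association while keeping T, N, N2, X and rho intact), the data
    are trimmed at each candidate threshold, and TReC-only per-cell-type
    eQTL tests are run.  The largest threshold whose empirical rejection
    rate at level ``alpha`` stays within the binomial noise envelope for
    every cell type is chosen; if none qualifies, the smallest is returned
    with a warning.  Returns (chosen, table) where table maps threshold ->
    per-cell-type rejection rates."""
    thresholds = list(candidate_thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("candidate thresholds must be strictly descending")
    rng = np.random.default_rng(seed)
    G = len(datasets)
    if G == 0:
        raise ValueError("no datasets supplied")
    Q = datasets[0].Q
    pvals = {c: [] for c in thresholds}
    from .fitting import fit_gene

    for data in datasets:
        perm = replace(data, Z=data.Z[rng.permutation(data.n)])
        C, null_params = cooks_distance(perm)
        Cn = normalize_cooks(C)
        imputed = np.maximum(np.round(_null_mu(null_params, perm)), 0.0)
        for c in thresholds:
            flag = Cn > c
            if np.any(flag):
                trimmed = replace(perm, T=np.where(flag, imputed, perm.T))
            else:
                trimmed = perm
            row = np.ones(Q)
            fit = fit_gene(trimmed, mode=mode)
            for q in range(Q):
                t = test_eqtl_celltype(trimmed, q, mode=mode, full_fit=fit)
                row[q] = t.p if t.testable else 1.0
            pvals[c].append(row)
    table = {c: np.mean(np.array(pvals[c]) < alpha, axis=0) for c in thresholds}
    tol = alpha + 2.0 * np.sqrt(alpha * (1.0 - alpha) / G)
    for c in thresholds:  # descending: largest first
        if np.all(table[c] <= tol):
            return c, table
    warnings.warn("no candidate threshold controls type I error; "
                  "returning the most aggressive one")
    return thresholds[-1], table
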