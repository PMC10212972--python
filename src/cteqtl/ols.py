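"""Interaction-OLS baseline for cell type-specific eQTL mapping.

The comparison approach regresses the inverse-normal-transformed,
depth-adjusted total read count on covariates, genotype dosage, cell type
proportions and genotype x proportion interactions:

    E[Tbar_i] = zeta0 + sum_j X_ij zeta_j + G_i zeta_g
              + sum_{q != ref} rho_iq gamma_q + G_i sum_{q != ref} rho_iq delta_q

The cell type-specific eQTL for a non-reference cell type q is assessed by
the Wald contrast zeta_g + delta_q = 0; the reference cell type's eQTL is
the marginal genotype test zeta_g = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm, rankdata


@dataclass
class OLSFit:
    result: object  # statsmodels RegressionResults
    reference: int
    Q: int
    names: list
    dropped: list


def inverse_normal_transform(T: np.ndarray,
                             read_depth: np.ndarray | None = None) -> np.ndarray:
    """Rank-based inverse normal transform of depth-adjusted counts.

    Counts are divided by the per-sample read depth (the 75th percentile
    of the sample's gene-level TReCs) when supplied, then mapped through
    average ranks to Phi^{-1}((rank - 0.5) / n).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if read_depth is not None:
        read_depth = np.asarray(read_depth, dtype=float)
        if np.any(read_depth <= 0):
            raise ValueError("read depth must be positive")
        T = T / read_depth
    ranks = rankdata(T, method="average")
    return norm.ppf((ranks - 0.5) / n)


def fit_ols(Tbar: np.ndarray, X: np.ndarray, G: np.ndarray,
            rho: np.ndarray, reference: int | None = None) -> OLSFit:
    """Least-squares fit of the interaction design.

    ``G`` is B-allele dosage in {0, 1, 2}.  The reference cell type
    (default: highest mean proportion) is excluded from the proportion and
    interaction columns.  Rank-deficient columns are dropped with a note.
    """
    Tbar = np.asarray(Tbar, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = np.asarray(G, dtype=float)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if not np.isin(G, [0, 1, 2]).all():
        raise ValueError("G must contain dosages 0, 1 or 2")
    Q = rho.shape[1]
    if reference is None:
        reference = int(np.argmax(rho.mean(axis=0)))
    others = [q for q in range(Q) if q != reference]
    cols = [np.ones_like(Tbar)]
    names = ["intercept"]
    for j in range(X.shape[1]):
        cols.append(X[:, j]); names.append(f"x{j}")
    cols.append(G); names.append("G")
    for q in others:
        cols.append(rho[:, q]); names.append(f"rho{q}")
    for q in others:
        cols.append(G * rho[:, q]); names.append(f"G:rho{q}")
    M = np.column_stack(cols)
    # drop columns that do not add rank (e.g. constant G or constant rho)
    dropped = []
    keep = [0]
    rank = 1
    for j in range(1, M.shape[1]):
        cand = M[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(names[j])
    res = sm.OLS(Tbar, M[:, keep]).fit()
    return OLSFit(result=res, reference=reference, Q=Q,
                  names=[names[j] for j in keep], dropped=dropped)


def ols_celltype_test(fit: OLSFit, q: int):
    """Wald test of the cell type-q eQTL contrast.

    Non-reference cell types test zeta_g + delta_q = 0; the reference cell
    type tests zeta_g = 0.  Returns (stat, p); (nan, 1) with untestable
    contrasts (dropped columns)."""
    names = fit.names
    if "G" not in names or (q != fit.reference and f"G:rho{q}" not in names):
        return float("nan"), 1.0
    k = len(names)
    contrast = np.zeros(k)
    contrast[names.index("G")] = 1.0
    if q != fit.reference:
        contrast[names.index(f"G:rho{q}")] = 1.0
    t = fit.result.t_test(contrast)
    return float(np.squeeze(t.tvalue)), float(np.squeeze(t.pvalue))
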