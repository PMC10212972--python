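"""Staged maximum-likelihood fitting of the joint TReC/ASReC model.

Parameters are estimated in six nested stages, each warm-started from the
previous one:

1. Poisson regression of TReC on covariates (mu_A1, beta), Newton-Raphson.
2. Negative binomial: add the overdispersion phi (initialized at 1).
3. Add cell type proportions: kappa_q free (initialized at 1), BFGS.
4. Add the phased genotype: eta_q free (initialized at 1), BFGS.
5. Add the allele-specific counts: psi free (initialized at 1), alpha = 1.
6. Free the cis/trans ratios alpha_q (cistrans mode only).

All positive parameters are optimized on the log scale, so the search is
unconstrained.  Convergence requires the score norm below eps1, an
invertible observed information with positive variances, and a Newton step
norm below eps2.  When a stage cannot converge, cell type-specific
parameters are pinned to their null values (kappa_q = 0 for effectively
unexpressed cell types, eta_q = 1, alpha_q = 1) following fixed rules, and
the affected stages are re-run with the reduced free set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import betaln, digamma, gammaln
from scipy.stats import chi2

from .models import (
    AA,
    AB,
    BA,
    BB,
    CSeQTLParams,
    DegenerateMixtureError,
    GeneSnpData,
    Mode,
    MODES,
    joint_loglik,
)

_LOG2 = float(np.log(2.0))

DEFAULT_EPS1 = 1e-3
DEFAULT_EPS2 = 1e-6
MAX_BFGS_ITER = 500
FD_STEP = 1e-5  # central-difference step for the score Jacobian (log scale)
BOUNDARY_TEST_LEVEL = 0.05


class NonExpressedGeneError(ValueError):
    """No cell type carries enough expression to fit an eQTL model."""


@dataclass
class ConstraintLedger:
    """Record of parameters pinned to null values during fitting."""

    Q: int
    kappa_zeroed: np.ndarray = None
    eta_fixed: np.ndarray = None
    alpha_fixed: np.ndarray = None
    reasons: list = field(default_factory=list)
    reference_index: int = 0
    output_reference: int = 0

    def __post_init__(self) -> None:
        if self.kappa_zeroed is None:
            self.kappa_zeroed = np.zeros(self.Q, dtype=bool)
        if self.eta_fixed is None:
            self.eta_fixed = np.zeros(self.Q, dtype=bool)
        if self.alpha_fixed is None:
            self.alpha_fixed = np.zeros(self.Q, dtype=bool)

    def zero_kappa(self, q: int, reason: str) -> None:
        if q == self.reference_index:
            raise ValueError("cannot zero the reference cell type")
        self.kappa_zeroed[q] = True
        self.fix_eta(q, reason)
        self.reasons.append(f"kappa[{q}]=0: {reason}")

    def fix_eta(self, q: int, reason: str) -> None:
        self.eta_fixed[q] = True
        self.alpha_fixed[q] = True
        self.reasons.append(f"eta[{q}]=1 (alpha[{q}]=1): {reason}")

    def fix_alpha(self, q: int, reason: str) -> None:
        self.alpha_fixed[q] = True
        self.reasons.append(f"alpha[{q}]=1: {reason}")

    def copy(self) -> "ConstraintLedger":
        out = ConstraintLedger(
            self.Q,
            self.kappa_zeroed.copy(),
            self.eta_fixed.copy(),
            self.alpha_fixed.copy(),
            list(self.reasons),
            self.reference_index,
            self.output_reference,
        )
        return out


@dataclass
class FitResult:
    params: CSeQTLParams
    ledger: ConstraintLedger
    loglik: float
    grad_norm: float
    step_norm: float
    cov: np.ndarray
    param_names: list
    converged: bool
    stage_reached: int
    mode: str
    use_phi: bool
    use_psi: bool
    message: str = ""

    def variance_of(self, name: str) -> float:
        """Variance of a free log-scale parameter, NaN if absent."""
        if self.cov is None or name not in self.param_names:
            return float("nan")
        i = self.param_names.index(name)
        return float(self.cov[i, i])


# ---------------------------------------------------------------------------
# free-parameter packing


class _Spec:
    """Layout of the free (log-scale) parameter vector for one stage."""

    def __init__(self, data, mode, stage, ledger, use_phi, use_psi):
        self.mode = mode
        self.stage = stage
        self.ledger = ledger
        self.Q = data.Q
        self.p = data.p
        self.use_phi = use_phi and stage >= 2
        self.has_ase = mode != "trec" and stage >= 5
        self.use_psi = use_psi and self.has_ase
        ref = ledger.reference_index
        self.free_kappa = [
            q for q in range(self.Q)
            if stage >= 3 and q != ref and not ledger.kappa_zeroed[q]
        ]
        self.free_eta = [
            q for q in range(self.Q)
            if stage >= 4 and not ledger.eta_fixed[q] and not ledger.kappa_zeroed[q]
        ]
        self.free_alpha = [
            q for q in range(self.Q)
            if mode == "cistrans" and stage >= 6 and not ledger.alpha_fixed[q]
        ]
        self.names = (
            ["log_mu_A1"]
            + [f"beta[{j}]" for j in range(self.p)]
            + (["log_phi"] if self.use_phi else [])
            + [f"log_kappa[{q}]" for q in self.free_kappa]
            + [f"log_eta[{q}]" for q in self.free_eta]
            + (["log_psi"] if self.use_psi else [])
            + [f"log_alpha[{q}]" for q in self.free_alpha]
        )
        self.k = len(self.names)
        self.kappa_base = np.where(ledger.kappa_zeroed, 0.0, 1.0)
        # data-dependent constants reused across likelihood evaluations
        Z, N, N2, T = data.Z, data.N, data.N2, data.T
        het = (Z == AB) | (Z == BA)
        obs = N > 0
        y = np.where(Z == BA, N - N2, N2)
        self.cache = {
            "het": het,
            "homB": Z == BB,
            "obs": obs,
            "obs_het": obs & het,
            "any_obs": bool(np.any(obs)),
            "No": N[obs],
            "yo": y[obs],
            "sum_lgT1": float(np.sum(gammaln(T + 1.0))),
            "sum_lbinom": float(np.sum(
                gammaln(N[obs] + 1.0) - gammaln(y[obs] + 1.0)
                - gammaln(N[obs] - y[obs] + 1.0)
            )),
        }

    def unpack_raw(self, x: np.ndarray):
        """Split the free vector into natural-scale parameter arrays."""
        i = 1 + self.p
        mu_A1 = float(np.exp(x[0]))
        beta = x[1:i]
        phi = 0.0
        if self.use_phi:
            phi = float(np.exp(x[i])); i += 1
        kappa = self.kappa_base.copy()
        nk = len(self.free_kappa)
        if nk:
            kappa[self.free_kappa] = np.exp(x[i:i + nk]); i += nk
        eta = np.ones(self.Q)
        ne = len(self.free_eta)
        if ne:
            eta[self.free_eta] = np.exp(x[i:i + ne]); i += ne
        psi = 0.0
        if self.use_psi:
            psi = float(np.exp(x[i])); i += 1
        alpha = np.ones(self.Q)
        na = len(self.free_alpha)
        if na:
            alpha[self.free_alpha] = np.exp(x[i:i + na])
        return mu_A1, beta, phi, kappa, eta, psi, alpha

    def pack(self, params: CSeQTLParams) -> np.ndarray:
        x = [np.log(params.mu_A1)]
        x.extend(params.beta)
        if self.use_phi:
            x.append(np.log(max(params.phi, 1e-8)))
        x.extend(np.log(params.kappa[self.free_kappa]))
        x.extend(np.log(params.eta[self.free_eta]))
        if self.use_psi:
            x.append(np.log(max(params.psi, 1e-8)))
        x.extend(np.log(params.alpha[self.free_alpha]))
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray) -> CSeQTLParams:
        mu_A1, beta, phi, kappa, eta, psi, alpha = self.unpack_raw(x)
        return CSeQTLParams(
            mu_A1=mu_A1, beta=beta.copy(), phi=phi, kappa=kappa, eta=eta,
            psi=psi, alpha=alpha, reference=self.ledger.reference_index,
        )


# ---------------------------------------------------------------------------
# negative log-likelihood and analytic score


def _nll_grad(x: np.ndarray, data: GeneSnpData, spec: _Spec):
    """Negative joint log-likelihood and its analytic gradient.

    Gradient blocks follow the free-vector layout of ``spec``; per-cell-type
    derivatives are assembled with matrix-vector products over the full Q
    columns and then restricted to the free indices.  Boundary evaluations
    (pi at 0 or 1, overflowing means) return +inf for the line search to
    back off, so floating-point warnings are suppressed."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return _nll_grad_impl(x, data, spec)


def _nll_grad_impl(x: np.ndarray, data: GeneSnpData, spec: _Spec):
    mu_A1, beta, phi, kappa, eta, psi, alpha = spec.unpack_raw(x)
    T, X, rho = data.T, data.X, data.rho
    c = spec.cache
    S = rho @ kappa
    if np.any(S <= 0) or not np.all(np.isfinite(S)):
        return np.inf, np.zeros(spec.k)
    xiT = (rho @ (eta * kappa)) / S
    log_mu = np.log(2.0 * mu_A1) + X @ beta + np.log(S)
    het, homB = c["het"], c["homB"]
    hp = np.zeros(data.n)  # d log(genotype factor) / d xi
    log_mu[het] += np.log1p(xiT[het]) - _LOG2
    log_mu[homB] += np.log(xiT[homB])
    hp[het] = 1.0 / (1.0 + xiT[het])
    hp[homB] = 1.0 / xiT[homB]
    mu = np.exp(log_mu)
    if not np.all(np.isfinite(mu)):
        return np.inf, np.zeros(spec.k)

    if spec.use_phi and phi > 1e-8:
        r = 1.0 / phi
        log_r_mu = np.log(r + mu)
        ll = np.sum(
            gammaln(T + r) + r * (np.log(r) - log_r_mu)
            + T * (log_mu - log_r_mu)
        ) - data.n * gammaln(r) - c["sum_lgT1"]
        w = T - mu * (T + r) / (mu + r)  # d ll_i / d log mu_i
        dldr = (
            digamma(T + r) - digamma(r) + np.log(r) + 1.0
            - log_r_mu - (r + T) / (r + mu)
        )
        g_lphi = float(np.sum(-r * dldr))
    else:
        ll = np.sum(T * log_mu - mu) - c["sum_lgT1"]
        w = T - mu
        g_lphi = 0.0

    A = rho * kappa / S[:, None]  # A_iq = rho_iq kappa_q / S_i
    whp = w * hp
    g_kappa = w @ A + eta * (whp @ A) - (whp * xiT) @ A
    g_eta = eta * (whp @ A)
    g_alpha = None
    g_lpsi = 0.0

    # --- allele-specific factor -------------------------------------------
    if spec.has_ase and c["any_obs"]:
        obs, ho = c["obs"], c["obs_het"]
        eta_a = eta * alpha if spec.mode == "cistrans" else eta
        xiA = (rho @ (eta_a * kappa)) / S
        pi = np.where(c["het"], xiA / (1.0 + xiA), 0.5)
        No, yo, pio = c["No"], c["yo"], pi[obs]
        if spec.use_psi and psi > 0:
            a = pio / psi
            b = (1.0 - pio) / psi
            ll += float(np.sum(betaln(yo + a, No - yo + b) - betaln(a, b))
                        + c["sum_lbinom"])
            d_ab = digamma(a + b) - digamma(No + a + b)
            dla = digamma(yo + a) - digamma(a) + d_ab
            dlb = digamma(No - yo + b) - digamma(b) + d_ab
            dldpi_o = (dla - dlb) / psi
            g_lpsi = float(np.sum(-a * dla - b * dlb))
        else:
            ll += float(np.sum(yo * np.log(pio) + (No - yo) * np.log1p(-pio))
                        + c["sum_lbinom"])
            dldpi_o = yo / pio - (No - yo) / (1.0 - pio)
        # dl/dxiA, nonzero only for observed heterozygotes
        u = np.zeros(data.n)
        u[obs] = dldpi_o
        u[~c["het"]] = 0.0
        u /= (1.0 + xiA) ** 2
        uA = u @ A
        g_kappa = g_kappa + eta_a * uA - (u * xiA) @ A
        g_eta = g_eta + eta_a * uA
        g_alpha = eta_a * uA

    if not np.isfinite(ll):
        return np.inf, np.zeros(spec.k)

    grad = np.empty(spec.k)
    i = 0
    grad[i] = np.sum(w); i += 1
    grad[i:i + spec.p] = X.T @ w; i += spec.p
    if spec.use_phi:
        grad[i] = g_lphi; i += 1
    nk = len(spec.free_kappa)
    grad[i:i + nk] = g_kappa[spec.free_kappa]; i += nk
    ne = len(spec.free_eta)
    grad[i:i + ne] = g_eta[spec.free_eta]; i += ne
    if spec.use_psi:
        grad[i] = g_lpsi; i += 1
    if spec.free_alpha:
        grad[i:] = (g_alpha if g_alpha is not None
                    else np.zeros(data.Q))[spec.free_alpha]
    return -float(ll), -grad


def observed_information(x, data, spec, step: float = FD_STEP) -> np.ndarray:
    """Observed information: central-difference Jacobian of the score."""
    k = x.shape[0]
    H = np.zeros((k, k))
    for j in range(k):
        xp = x.copy(); xp[j] += step
        xm = x.copy(); xm[j] -= step
        gp = _nll_grad(xp, data, spec)[1]
        gm = _nll_grad(xm, data, spec)[1]
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def check_convergence(grad, hessian, eps1: float = DEFAULT_EPS1,
                      eps2: float = DEFAULT_EPS2):
    """Convergence verdict: small score, invertible information with
    positive variances, and a small Newton step.

    Returns (converged, grad_norm, step_norm, reason)."""
    gnorm = float(np.linalg.norm(grad))
    if not np.all(np.isfinite(hessian)):
        return False, gnorm, np.inf, "non-finite information"
    try:
        cov = np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        return False, gnorm, np.inf, "non-invertible"
    if np.linalg.cond(hessian) > 1e12:
        return False, gnorm, np.inf, "non-invertible"
    if np.any(np.diag(cov) <= 0):
        return False, gnorm, np.inf, "negative variance"
    step = cov @ grad
    snorm = float(np.linalg.norm(step))
    ok = gnorm < eps1 and snorm < eps2
    reason = "" if ok else "thresholds not met"
    return ok, gnorm, snorm, reason


# ---------------------------------------------------------------------------
# optimizers


def _newton(x0, data, spec, max_iter=100, tol=1e-10):
    """Damped Newton-Raphson on the negative log-likelihood."""
    x = x0.copy()
    f, g = _nll_grad(x, data, spec)
    for _ in range(max_iter):
        H = observed_information(x, data, spec)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            # singular information (e.g. a constant covariate column):
            # take the minimum-norm Newton step
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            break
        t = 1.0
        for _ls in range(30):
            f_new, g_new = _nll_grad(x - t * step, data, spec)
            if f_new <= f + 1e-12:
                break
            t *= 0.5
        else:
            break
        x = x - t * step
        f, g = f_new, g_new
        if np.linalg.norm(t * step) < tol:
            break
    return x, f, g


def _maximize(x0, data, spec, polish_iter=30):
    """BFGS followed by a Newton polish to meet the convergence criteria.

    ``polish_iter=0`` skips the (Hessian-based) polish when BFGS already
    drove the score norm well below the convergence threshold; warm-started
    intermediate stages use this fast path."""
    res = optimize.minimize(
        _nll_grad, x0, args=(data, spec), jac=True, method="BFGS",
        options={"maxiter": MAX_BFGS_ITER, "gtol": 1e-6},
    )
    x = res.x
    f, g = _nll_grad(x, data, spec)
    if not np.isfinite(f):
        x = x0.copy()
        f, g = _nll_grad(x, data, spec)
    if polish_iter == 0:
        polish_iter = 0 if np.linalg.norm(g) < 1e-4 else 3
    for _ in range(polish_iter):
        if np.linalg.norm(g) < 1e-12:
            break
        H = observed_information(x, data, spec)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        t = 1.0
        accepted = False
        for _ls in range(25):
            f_new, g_new = _nll_grad(x - t * step, data, spec)
            if f_new <= f + 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        x = x - t * step
        f, g = f_new, g_new
        if np.linalg.norm(t * step) < 1e-12:
            break
    return x, f, g


# ---------------------------------------------------------------------------
# reference swapping


def swap_reference(params: CSeQTLParams, new_ref: int) -> CSeQTLParams:
    """Re-express the parameters against a new reference cell type.

    mu_A1' = mu_A1 * kappa[new_ref]; kappa' = kappa / kappa[new_ref].
    eta and alpha are per-cell-type ratios, so they are unchanged, and the
    likelihood is invariant."""
    if params.kappa[new_ref] <= 0:
        raise ValueError("cannot use a zeroed cell type as reference")
    out = params.copy()
    k_r = params.kappa[new_ref]
    out.mu_A1 = params.mu_A1 * k_r
    out.kappa = params.kappa / k_r
    out.reference = new_ref
    return out


# ---------------------------------------------------------------------------
# boundary test for overdispersion


def _keep_overdispersion(ll_full: float, ll_reduced: float) -> bool:
    """Boundary LRT for phi = 0 (or psi = 0): the null distribution is a
    50:50 mixture of a point mass at 0 and chi-square(1)."""
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    p = 0.5 * chi2.sf(stat, df=1)
    return p < BOUNDARY_TEST_LEVEL


# ---------------------------------------------------------------------------
# the staged fit


def fit_stage(data: GeneSnpData, params: CSeQTLParams, stage: int,
              mode: Mode = "cis", ledger: ConstraintLedger | None = None,
              use_phi: bool = True, use_psi: bool = True,
              polish_iter: int = 25):
    """Fit one stage of the nested scheme, warm-started from ``params``.

    Returns (params, loglik, spec, x, grad)."""
    if stage not in range(1, 7):
        raise ValueError("stage must be in 1..6")
    if ledger is None:
        ledger = ConstraintLedger(data.Q, reference_index=params.reference,
                                  output_reference=params.reference)
    spec = _Spec(data, mode, stage, ledger, use_phi, use_psi)
    x0 = spec.pack(params)
    f0, _ = _nll_grad(x0, data, spec)
    if not np.isfinite(f0):
        raise FloatingPointError(
            f"non-finite log-likelihood at the start of stage {stage}"
        )
    if stage <= 2:
        x, f, g = _newton(x0, data, spec)
    else:
        x, f, g = _maximize(x0, data, spec, polish_iter=polish_iter)
    return spec.unpack(x), -f, spec, x, g


def fit_null_trec(data: GeneSnpData):
    """Fit the genotype-free TReC model (stages 1-3): mu_A1, beta, phi,
    kappa.  Used as the null model for influence diagnostics and imputation.

    Returns (params, spec, x, loglik, ledger, use_phi)."""
    if np.all(data.T == 0):
        raise NonExpressedGeneError("all total read counts are zero")
    ref = int(np.argmax(data.rho.mean(axis=0)))
    ledger = ConstraintLedger(data.Q, reference_index=ref, output_reference=ref)
    base = CSeQTLParams(
        mu_A1=max(float(np.mean(data.T)), 0.5) / 2.0,
        beta=np.zeros(data.p), kappa=np.ones(data.Q), reference=ref,
    )
    p1, ll1, *_ = fit_stage(data, base, 1, mode="trec", ledger=ledger,
                            use_phi=False, use_psi=False)
    p2 = p1.copy()
    p2.phi = 1.0
    p2, ll2, *_ = fit_stage(data, p2, 2, mode="trec", ledger=ledger,
                            use_phi=True, use_psi=False)
    use_phi = _keep_overdispersion(ll2, ll1)
    params = (p2 if use_phi else p1).copy()
    for _ in range(data.Q + 1):
        params.kappa = np.where(ledger.kappa_zeroed, 0.0, 1.0)
        params, ll, spec, x, _g = fit_stage(
            data, params, 3, mode="trec", ledger=ledger,
            use_phi=use_phi, use_psi=False,
        )
        mu_AA = 2.0 * params.mu_A1 * params.kappa
        weak = (mu_AA < 2.0) & ~ledger.kappa_zeroed
        weak[ledger.reference_index] = False
        if not np.any(weak):
            break
        for q in np.nonzero(weak)[0]:
            ledger.zero_kappa(int(q), f"mu_AA[{q}] = {mu_AA[q]:.3g} < 2")
    return params, spec, x, ll, ledger, use_phi


def fit_gene(
    data: GeneSnpData,
    mode: Mode = "cis",
    eps1: float = DEFAULT_EPS1,
    eps2: float = DEFAULT_EPS2,
    fix_eta: tuple = (),
    fix_alpha: tuple = (),
    init_params: CSeQTLParams | None = None,
    use_phi: bool | None = None,
    use_psi: bool | None = None,
    base_ledger: ConstraintLedger | None = None,
) -> FitResult:
    """Full staged fit of one gene-SNP pair with identifiability handling.

    ``fix_eta`` / ``fix_alpha`` pin the named cell types' effects to 1
    (used for likelihood-ratio null fits).  ``use_phi`` / ``use_psi`` force
    the overdispersion reduction decisions (None: decide by the boundary
    test); a nested null fit should inherit them from the full fit.  The
    returned parameters are expressed against the cell type with the
    highest average proportion.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if np.all(data.T == 0):
        raise NonExpressedGeneError("all total read counts are zero")
    output_ref = int(np.argmax(data.rho.mean(axis=0)))
    ledger = ConstraintLedger(data.Q, reference_index=output_ref,
                              output_reference=output_ref)
    if base_ledger is not None:
        # inherit the full model's pinned parameters so that a null fit is
        # nested within it
        ledger.kappa_zeroed |= base_ledger.kappa_zeroed
        ledger.eta_fixed |= base_ledger.eta_fixed
        ledger.alpha_fixed |= base_ledger.alpha_fixed
        ledger.reasons.extend(base_ledger.reasons)
        if ledger.kappa_zeroed[output_ref]:
            order = np.argsort(-data.rho.mean(axis=0))
            ledger.reference_index = int(
                next(q for q in order if not ledger.kappa_zeroed[q]))
    for q in fix_eta:
        ledger.fix_eta(int(q), "fixed by caller")
    for q in fix_alpha:
        ledger.fix_alpha(int(q), "fixed by caller")

    # stages 1-2: covariate-only Poisson, then NB, then the boundary test
    base = CSeQTLParams(
        mu_A1=max(float(np.mean(data.T)), 0.5) / 2.0,
        beta=np.zeros(data.p),
        phi=0.0,
        kappa=np.ones(data.Q),
        reference=output_ref,
    )
    if init_params is not None and use_phi is not None:
        # warm start: skip the covariate-only stages
        theta2 = CSeQTLParams(
            mu_A1=init_params.mu_A1, beta=init_params.beta.copy(),
            phi=init_params.phi if use_phi else 0.0,
            kappa=np.ones(data.Q), reference=output_ref,
        )
        ll2 = joint_loglik(data, theta2, "trec")
    else:
        p1, ll1, *_ = fit_stage(data, base, 1, mode=mode, ledger=ledger,
                                use_phi=False, use_psi=False)
        p2 = p1.copy()
        p2.phi = 1.0
        p2, ll2, *_ = fit_stage(data, p2, 2, mode=mode, ledger=ledger,
                                use_phi=True, use_psi=False)
        if use_phi is None:
            use_phi = _keep_overdispersion(ll2, ll1)
        theta2 = p2 if use_phi else p1
        if not use_phi:
            theta2 = theta2.copy()
            theta2.phi = 0.0

    force_psi = use_psi
    use_psi = True if force_psi is None else force_psi

    # fast path for nested null fits: with a warm start at the full fit's
    # optimum and inherited reduction decisions, a single final-stage fit
    # usually converges; fall back to the staged procedure otherwise
    if init_params is not None and use_phi is not None and \
            force_psi is not None:
        final = {"trec": 4, "cis": 5, "cistrans": 6}[mode]
        try:
            warm = init_params.copy()
            if warm.reference != ledger.reference_index:
                warm = swap_reference(warm, ledger.reference_index)
            warm.kappa = np.where(ledger.kappa_zeroed, 0.0, warm.kappa)
            warm.eta = np.where(ledger.eta_fixed, 1.0, warm.eta)
            warm.alpha = np.where(ledger.alpha_fixed, 1.0, warm.alpha)
            if not use_phi:
                warm.phi = 0.0
            if not use_psi:
                warm.psi = 0.0
            params, ll, spec, x, g = fit_stage(
                data, warm, final, mode=mode, ledger=ledger,
                use_phi=use_phi, use_psi=use_psi,
            )
            H = observed_information(x, data, spec)
            converged, gnorm, snorm, _why = check_convergence(
                -np.asarray(g), H, eps1, eps2)
            if converged:
                result = FitResult(
                    params=params, ledger=ledger, loglik=ll,
                    grad_norm=gnorm, step_norm=snorm,
                    cov=np.linalg.inv(H), param_names=spec.names,
                    converged=True, stage_reached=final, mode=mode,
                    use_phi=use_phi, use_psi=use_psi,
                )
                if result.params.reference != output_ref and not \
                        result.ledger.kappa_zeroed[output_ref]:
                    result.params = swap_reference(result.params,
                                                   output_ref)
                return result
        except (FloatingPointError, DegenerateMixtureError,
                ValueError):
            pass
    stage_reached = 2
    result = None
    for _pass in range(data.Q + 3):
        try:
            # ----- stage 3: kappa ----------------------------------------
            params = theta2.copy()
            params.kappa = np.where(ledger.kappa_zeroed, 0.0, 1.0)
            params.kappa[ledger.reference_index] = 1.0
            if init_params is not None and _pass == 0:
                free = ~ledger.kappa_zeroed
                params.kappa[free] = np.maximum(init_params.kappa[free], 1e-6)
                params.kappa /= params.kappa[ledger.reference_index]
            params, ll3, spec3, x3, g3 = fit_stage(
                data, params, 3, mode=mode, ledger=ledger,
                use_phi=use_phi, use_psi=False, polish_iter=0,
            )
            stage_reached = 3
            # kappa rule: each haplotype must express at least one read
            mu_AA = 2.0 * params.mu_A1 * params.kappa
            weak = (mu_AA < 2.0) & ~ledger.kappa_zeroed
            weak[ledger.reference_index] = False
            if np.any(weak):
                for q in np.nonzero(weak)[0]:
                    ledger.zero_kappa(int(q), f"mu_AA[{q}] = {mu_AA[q]:.3g} < 2")
                if np.all(ledger.kappa_zeroed | (mu_AA < 2.0)):
                    raise NonExpressedGeneError(
                        "all cell types fall below one read per haplotype"
                    )
                continue
            if np.all(ledger.kappa_zeroed[
                    [q for q in range(data.Q) if q != ledger.reference_index]]) \
                    and mu_AA[ledger.reference_index] < 2.0:
                raise NonExpressedGeneError("reference cell type not expressed")

            # internal reference: the cell type with the highest TReC
            best = int(np.argmax(np.where(ledger.kappa_zeroed, -np.inf,
                                          params.kappa)))
            if best != ledger.reference_index:
                params = swap_reference(params, best)
                ledger.reference_index = best

            # ----- stage 4: eta ------------------------------------------
            params4 = params.copy()
            params4.eta = np.ones(data.Q)
            if init_params is not None and _pass == 0:
                free_eta = ~(ledger.eta_fixed | ledger.kappa_zeroed)
                params4.eta[free_eta] = init_params.eta[free_eta]
            params, ll, spec, x, g = fit_stage(
                data, params4, 4, mode=mode, ledger=ledger,
                use_phi=use_phi, use_psi=False,
                polish_iter=25 if mode == "trec" else 0,
            )
            stage_reached = 4

            if mode != "trec":
                # ----- stage 5: psi (alpha = 1) --------------------------
                if force_psi is not False:
                    params5 = params.copy()
                    params5.psi = (init_params.psi if init_params is not None
                                   and init_params.psi > 0 else 1.0)
                    params5, ll5, spec5, x5, g5 = fit_stage(
                        data, params5, 5, mode=mode, ledger=ledger,
                        use_phi=use_phi, use_psi=True,
                        polish_iter=0 if force_psi is None else 25,
                    )
                if force_psi is not True:
                    # binomial ASE fit (psi = 0)
                    p5b, ll5b, spec5b, x5b, g5b = fit_stage(
                        data, params.copy(), 5, mode=mode, ledger=ledger,
                        use_phi=use_phi, use_psi=False,
                        polish_iter=0 if force_psi is None else 25,
                    )
                if force_psi is None:
                    use_psi = _keep_overdispersion(ll5, ll5b)
                if use_psi:
                    params, ll, spec, x, g = params5, ll5, spec5, x5, g5
                else:
                    params, ll, spec, x, g = p5b, ll5b, spec5b, x5b, g5b
                if force_psi is None and mode == "cis":
                    # polish the selected stage-5 fit for the final verdict
                    params, ll, spec, x, g = fit_stage(
                        data, params, 5, mode=mode, ledger=ledger,
                        use_phi=use_phi, use_psi=use_psi, polish_iter=25,
                    )
                stage_reached = 5

            if mode == "cistrans":
                params6 = params.copy()
                params6.alpha = np.ones(data.Q)
                params, ll, spec, x, g = fit_stage(
                    data, params6, 6, mode=mode, ledger=ledger,
                    use_phi=use_phi, use_psi=use_psi,
                )
                stage_reached = 6
        except (FloatingPointError, DegenerateMixtureError) as exc:
            # treat as non-convergence of the current pass; no variance
            # information is available for the rules below
            H = None
            converged, gnorm, snorm, reason = False, np.inf, np.inf, str(exc)
            params, ll = theta2, ll2
            spec = x = g = None
        # ----- convergence verdict ---------------------------------------
        if spec is not None:
            H = observed_information(x, data, spec)
            converged, gnorm, snorm, reason = check_convergence(
                -np.asarray(g), H, eps1, eps2
            )
        if spec is not None and converged:
            cov = np.linalg.inv(H)
            result = FitResult(
                params=params, ledger=ledger, loglik=ll, grad_norm=gnorm,
                step_norm=snorm, cov=cov, param_names=spec.names,
                converged=True, stage_reached=stage_reached, mode=mode,
                use_phi=use_phi, use_psi=use_psi,
            )
            break

        # ----- identifiability rules on failure ---------------------------
        progressed = False
        if spec is not None:
            try:
                cov = np.linalg.pinv(H)
            except np.linalg.LinAlgError:
                cov = np.full((spec.k, spec.k), np.nan)
            # eta rule: near-zero allelic mean or negative variance
            mu_A = params.mu_A1 * params.kappa
            mu_B = mu_A * params.eta
            mu_z = np.minimum(mu_A, mu_B)
            for q in range(data.Q):
                if ledger.eta_fixed[q] or ledger.kappa_zeroed[q]:
                    continue
                name = f"log_eta[{q}]"
                var = (cov[spec.names.index(name), spec.names.index(name)]
                       if name in spec.names else np.nan)
                if (0.0 < mu_z[q] < 1.0) or (np.isfinite(var) and var < 0):
                    ledger.fix_eta(q, f"mu_z[{q}] = {mu_z[q]:.3g} in (0,1) "
                                      f"or negative variance")
                    progressed = True
            # alpha rule
            if not progressed and mode == "cistrans" and stage_reached >= 6:
                alpha_vars = {}
                for q in range(data.Q):
                    if ledger.alpha_fixed[q]:
                        continue
                    name = f"log_alpha[{q}]"
                    if name in spec.names:
                        i = spec.names.index(name)
                        alpha_vars[q] = cov[i, i]
                neg = [q for q, v in alpha_vars.items()
                       if np.isfinite(v) and v < 0]
                if neg:
                    for q in neg:
                        ledger.fix_alpha(q, "negative variance")
                    progressed = True
                elif alpha_vars:
                    q = max(alpha_vars, key=lambda qq: alpha_vars[qq])
                    ledger.fix_alpha(q, "largest variance, non-converged")
                    progressed = True
        if not progressed:
            # nothing left to pin: report the non-converged fit as-is
            cov = (np.linalg.pinv(H) if spec is not None else None)
            result = FitResult(
                params=params if spec is not None else theta2,
                ledger=ledger, loglik=ll if spec is not None else ll2,
                grad_norm=gnorm, step_norm=snorm, cov=cov,
                param_names=spec.names if spec is not None else [],
                converged=False, stage_reached=stage_reached, mode=mode,
                use_phi=use_phi, use_psi=use_psi, message=reason,
            )
            break
    if result is None:
        raise RuntimeError("constraint loop exhausted without a fit")

    # final output against the highest-mean-proportion cell type
    if result.params.reference != output_ref and not \
            result.ledger.kappa_zeroed[output_ref]:
        result.params = swap_reference(result.params, output_ref)
    return result
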