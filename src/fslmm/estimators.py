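"""The five Fisher-scoring fitting algorithms for the crossed-factor LMM.

Methods
-------
``fs``
    Joint scoring update of ``(beta, s2, vech(D_1), ..., vech(D_r))`` using
    the half-representation score and expected information.
``ffs``
    Joint update in the full representation ``vec(D_k)``; the expected
    information is rank-deficient there, so the update inverts the scoring
    matrix ``F`` instead, which reproduces the pseudo-inverse update.
``sfs``
    Per-iteration generalized least squares for ``(beta, s2)`` followed by
    one scoring step on each ``vech(D_k)`` using that factor's diagonal
    information block.
``fsfs``
    As ``sfs`` but updating ``vec(D_k)`` with the ``F`` block.
``csfs``
    As ``sfs`` but updating ``vech(Lambda_k)`` (Cholesky factors), so
    ``D_k = Lambda_k Lambda_k'`` is positive semi-definite by construction
    and never needs projection.

Shared machinery: OLS-based starting values; a step-halving safeguard
(start at step size 1, halve up to ``max_halvings`` times if the criterion
does not increase, accept a zero step with a warning otherwise);
eigenvalue-clipping projection of each ``D_k`` onto the PSD cone after
every update (except ``csfs``); convergence when successive log-likelihood
values differ by less than ``tol``.  The ``sfs``/``fsfs``/``csfs`` fits run
one final GLS pass for ``(beta, s2)`` at the converged covariance.

Under the ReML criterion the GLS residual-variance update divides by
``n - p`` (the stationarity point of the adjusted score); ML divides by
``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .derivatives import fisher_information, score
from .matcalc import unvec, unvech, vec, vech
from .model import (
    SIGMA2_FLOOR,
    CovarianceParams,
    LMMDesign,
    ProductForms,
    chol_factor,
    core_solves,
    log_likelihood,
    product_forms,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "METHODS",
    "initial_values",
    "gls_update",
    "project_psd",
    "fit",
]

METHODS = ("fs", "ffs", "sfs", "fsfs", "csfs")
_PINV_RCOND = 1e-12


@dataclass
class FitConfig:
    """Optimizer settings; fits are deterministic given the inputs."""

    method: str = "fsfs"
    reml: bool = False
    tol: float = 1e-6
    max_iter: int = 200
    max_halvings: int = 10
    psd_project: bool = True

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FitResult:
    """Converged (or best-effort) parameter estimates and diagnostics."""

    beta: np.ndarray
    sigma2: float
    Dk_list: list[np.ndarray]
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    method: str
    reml: bool
    warnings: list[str] = field(default_factory=list)
    Lambda_list: list[np.ndarray] | None = None

    @property
    def llf(self) -> float:
        return self.loglik_trace[-1]

    def cov_params(self) -> CovarianceParams:
        return CovarianceParams(self.sigma2, self.Dk_list)


def project_psd(Dk: np.ndarray) -> np.ndarray:
    """Frobenius-nearest PSD matrix: eigendecompose and clip negatives."""
    Dk = np.asarray(Dk, dtype=float)
    Dk = 0.5 * (Dk + Dk.T)
    w, v = np.linalg.eigh(Dk)
    if w.min() >= 0:
        return Dk
    return (v * np.clip(w, 0.0, None)) @ v.T


def _stacked_diag_blocks(pf: ProductForms, M: np.ndarray, k: int) -> np.ndarray:
    """(l_k, q_k, q_k) array of the (k,j),(k,j) diagonal blocks of M."""
    fs = pf.fs
    sl = fs.factor_slice(k)
    sub = M[sl, sl].reshape(fs.l[k], fs.q[k], fs.l[k], fs.q[k])
    return np.einsum("jajb->jab", sub)


def initial_values(
    pf: ProductForms, psd_project: bool = True
) -> tuple[np.ndarray, float, list[np.ndarray], list[str]]:
    """OLS starting values for beta and s2, moment-style start for each D_k.

    ``beta_0 = (X'X)^{-1}X'Y`` and ``s2_0 = e_0'e_0/n``; each ``D_{k,0}``
    solves the Gram system
    ``(sum_j U_jj (x) U_jj) vec(D_k0) = vec(sum_j Z_(k,j)'(e0 e0'/s2_0 - I) Z_(k,j))``
    evaluated through the product forms, then is symmetrized and projected
    onto the PSD cone.  A singular Gram system falls back to ``D_{k,0} = 0``.
    """
    warns: list[str] = []
    try:
        beta0 = np.linalg.solve(pf.P, pf.Q)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("X'X is singular; X must have full rank") from err
    ete = float(pf.S - 2.0 * beta0 @ pf.Q + beta0 @ pf.P @ beta0)
    sigma2_0 = ete / pf.n
    if sigma2_0 <= SIGMA2_FLOOR:
        sigma2_0 = SIGMA2_FLOOR
        warns.append("initial sigma2 hit the evaluation floor (exact fit?)")
    Zte = pf.T - pf.R.T @ beta0
    Dk0 = []
    for k in range(pf.fs.r):
        qk, lk = pf.fs.q[k], pf.fs.l[k]
        a = Zte[pf.fs.factor_slice(k)].reshape(lk, qk)
        Ublocks = _stacked_diag_blocks(pf, pf.U, k)
        rhs_mat = np.einsum("ja,jb->ab", a, a) / sigma2_0 - Ublocks.sum(axis=0)
        gram = np.einsum("jab,jcd->acbd", Ublocks, Ublocks).reshape(qk * qk, qk * qk)
        try:
            v0 = np.linalg.solve(gram, vec(rhs_mat))
            D0 = unvec(v0, qk, qk)
        except np.linalg.LinAlgError:
            D0 = np.zeros((qk, qk))
            warns.append(f"factor {k}: singular initial Gram system, D_k0 = 0")
        D0 = 0.5 * (D0 + D0.T)
        if psd_project:
            D0 = project_psd(D0)
        Dk0.append(D0)
    return beta0, sigma2_0, Dk0, warns


def gls_update(
    pf: ProductForms,
    params: CovarianceParams,
    reml: bool = False,
    cs=None,
) -> tuple[np.ndarray, float]:
    """GLS estimates ``beta = (X'V^{-1}X)^{-1}X'V^{-1}Y``, ``s2 = e'V^{-1}e/n``.

    Under ReML the denominator is ``n - p``.
    """
    if cs is None:
        cs = core_solves(pf, params)
    beta = np.linalg.solve(cs.XtVinvX, cs.XtVinvY)
    denom = pf.n - pf.p if reml else pf.n
    sigma2 = cs.et_Vinv_e(beta) / denom
    return beta, float(sigma2)


def _solve_direction(M: np.ndarray, g: np.ndarray, warns: list[str], label: str):
    try:
        d = np.linalg.solve(M, g)
        if np.all(np.isfinite(d)):
            return d
    except np.linalg.LinAlgError:
        pass
    warns.append(f"singular {label} block: pseudo-inverse fallback")
    return np.linalg.pinv(M, rcond=_PINV_RCOND) @ g


def _safe_loglik(pf, sigma2, Dk_list, beta, reml):
    try:
        return log_likelihood(pf, CovarianceParams(sigma2, Dk_list), beta, reml=reml)
    except np.linalg.LinAlgError:
        return -np.inf


def fit(data: LMMDesign | ProductForms, config: FitConfig | None = None, **kwargs) -> FitResult:
    """Fit the LMM by the configured Fisher-scoring variant.

    ``data`` may be a design (product forms are built and the n-sized
    arrays dropped) or precomputed :class:`ProductForms`.  Keyword
    arguments are forwarded to :class:`FitConfig` when no config is given.
    """
    if config is None:
        config = FitConfig(**kwargs)
    pf = product_forms(data) if isinstance(data, LMMDesign) else data
    if pf.n <= pf.p:
        raise ValueError("need n > p observations")
    if np.linalg.matrix_rank(pf.P) < pf.p:
        raise np.linalg.LinAlgError("X is rank deficient")
    if config.method in ("fs", "ffs"):
        return _fit_joint(pf, config)
    return _fit_simplified(pf, config)


# ---------------------------------------------------------------------------
# joint updates (FS, FFS)
# ---------------------------------------------------------------------------


def _fit_joint(pf: ProductForms, config: FitConfig) -> FitResult:
    rep = "half" if config.method == "fs" else "full"
    fs = pf.fs
    beta, sigma2, Dk, warns = initial_values(pf, config.psd_project)
    ll = _safe_loglik(pf, sigma2, Dk, beta, config.reml)
    trace = [ll]
    converged = False
    n_iter = 0
    for _ in range(config.max_iter):
        n_iter += 1
        params = CovarianceParams(sigma2, Dk)
        cs = core_solves(pf, params)
        sv = score(pf, params, beta, rep=rep, reml=config.reml, cs=cs)
        im = fisher_information(
            pf, params, rep=rep, scoring_matrix=(rep == "full"),
            reml=config.reml, cs=cs,
        )
        d_beta = _solve_direction(im.beta_block, sv.d_beta, warns, "beta")
        g_cov = np.concatenate([[sv.d_sigma2], *sv.d_cov])
        d_cov = _solve_direction(im.cov_matrix(), g_cov, warns, "covariance")
        new = _try_step_joint(
            pf, config, beta, sigma2, Dk, ll, d_beta, d_cov, rep, warns
        )
        beta, sigma2, Dk, ll_new = new
        trace.append(ll_new)
        if abs(ll_new - ll) < config.tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    if not converged:
        warns.append("maximum number of iterations reached")
    if sigma2 <= SIGMA2_FLOOR:
        warns.append("sigma2 at the evaluation floor")
    return FitResult(
        beta=beta, sigma2=sigma2, Dk_list=Dk, loglik_trace=trace,
        n_iter=n_iter, converged=converged, method=config.method,
        reml=config.reml, warnings=warns,
    )


def _try_step_joint(pf, config, beta, sigma2, Dk, ll, d_beta, d_cov, rep, warns):
    fs = pf.fs
    alpha = 1.0
    for _ in range(config.max_halvings + 1):
        beta_new = beta + alpha * d_beta
        sigma2_new = sigma2 + alpha * d_cov[0]
        if sigma2_new <= SIGMA2_FLOOR:
            sigma2_new = SIGMA2_FLOOR
        Dk_new, pos = [], 1
        for k in range(fs.r):
            qk = fs.q[k]
            m = qk * (qk + 1) // 2 if rep == "half" else qk * qk
            step = d_cov[pos : pos + m]
            pos += m
            if rep == "half":
                D = unvech(vech(Dk[k]) + alpha * step, qk)
            else:
                D = unvec(vec(Dk[k]) + alpha * step, qk, qk)
                D = 0.5 * (D + D.T)
            if config.psd_project:
                D = project_psd(D)
            Dk_new.append(D)
        ll_new = _safe_loglik(pf, sigma2_new, Dk_new, beta_new, config.reml)
        if ll_new >= ll:
            return beta_new, sigma2_new, Dk_new, ll_new
        alpha *= 0.5
    warns.append("step halving exhausted; zero step accepted")
    return beta, sigma2, Dk, ll


# ---------------------------------------------------------------------------
# simplified updates (SFS, FSFS, CSFS)
# ---------------------------------------------------------------------------


def _fit_simplified(pf: ProductForms, config: FitConfig) -> FitResult:
    fs = pf.fs
    method = config.method
    beta, sigma2, Dk, warns = initial_values(pf, psd_project=True)
    lambdas = None
    if method == "csfs":
        lambdas = []
        for k, D in enumerate(Dk):
            try:
                lam = np.linalg.cholesky(D + 0.0)
            except np.linalg.LinAlgError:
                lam = chol_factor(D)
                warns.append(
                    f"factor {k}: rank-deficient start, QR-retriangularized root"
                )
            # a zero diagonal entry freezes its whole Cholesky column (zero
            # gradient coordinate); nudge such entries off the boundary
            scale = np.sqrt(max(np.trace(D) / D.shape[0], 1e-6))
            small = np.abs(np.diag(lam)) < 1e-3 * scale
            if np.any(small):
                lam = lam + np.diag(np.where(small, 1e-2 * scale, 0.0))
                warns.append(f"factor {k}: Cholesky start nudged off the boundary")
            lambdas.append(lam)
        Dk = [lam @ lam.T for lam in lambdas]
    ll = _safe_loglik(pf, sigma2, Dk, beta, config.reml)
    trace = [ll]
    converged = False
    n_iter = 0
    rep = {"sfs": "half", "fsfs": "full", "csfs": "chol"}[method]
    for _ in range(config.max_iter):
        n_iter += 1
        params = CovarianceParams(sigma2, Dk)
        cs = core_solves(pf, params)
        beta, sigma2 = gls_update(pf, params, reml=config.reml, cs=cs)
        if sigma2 <= SIGMA2_FLOOR:
            sigma2 = SIGMA2_FLOOR
            warns.append("sigma2 at the evaluation floor")
        params = CovarianceParams(sigma2, Dk)
        sv = score(pf, params, beta, rep=rep, reml=config.reml, cs=cs, lambdas=lambdas)
        im = fisher_information(
            pf, params, rep=rep, scoring_matrix=(rep == "full"),
            reml=config.reml, cs=cs, lambdas=lambdas,
        )
        dirs = [
            _solve_direction(im.cov_blocks[(k, k)], sv.d_cov[k], warns, f"D_{k}")
            for k in range(fs.r)
        ]
        ll_ref = log_likelihood(pf, params, beta, reml=config.reml, cs=cs)
        Dk, lambdas, ll_new = _try_step_cov(
            pf, config, sigma2, beta, Dk, lambdas, dirs, rep, ll_ref, warns
        )
        trace.append(ll_new)
        if abs(ll_new - ll) < config.tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    if not converged:
        warns.append("maximum number of iterations reached")
    # one final GLS pass at the converged covariance
    params = CovarianceParams(sigma2, Dk)
    beta, sigma2 = gls_update(pf, params, reml=config.reml)
    trace.append(_safe_loglik(pf, sigma2, Dk, beta, config.reml))
    return FitResult(
        beta=beta, sigma2=sigma2, Dk_list=Dk, loglik_trace=trace,
        n_iter=n_iter, converged=converged, method=method, reml=config.reml,
        warnings=warns, Lambda_list=lambdas,
    )


def _try_step_cov(pf, config, sigma2, beta, Dk, lambdas, dirs, rep, ll, warns):
    fs = pf.fs
    alpha = 1.0
    for _ in range(config.max_halvings + 1):
        Dk_new, lam_new = [], None
        if rep == "chol":
            lam_new = []
            for k in range(fs.r):
                lam = unvech(
                    vech(lambdas[k]) + alpha * dirs[k], fs.q[k], symmetric=False
                )
                lam_new.append(lam)
                Dk_new.append(lam @ lam.T)
        else:
            for k in range(fs.r):
                qk = fs.q[k]
                if rep == "half":
                    D = unvech(vech(Dk[k]) + alpha * dirs[k], qk)
                else:
                    D = unvec(vec(Dk[k]) + alpha * dirs[k], qk, qk)
                    D = 0.5 * (D + D.T)
                if config.psd_project:
                    D = project_psd(D)
                Dk_new.append(D)
        ll_new = _safe_loglik(pf, sigma2, Dk_new, beta, config.reml)
        if ll_new >= ll:
            return Dk_new, lam_new, ll_new
        alpha *= 0.5
    warns.append("step halving exhausted; zero step accepted")
    return Dk, lambdas, ll
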