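"""Approximate T-tests on fixed-effect contrasts with Satterthwaite dof.

For a ``(1 x p)`` contrast ``L`` the statistic is

    T = L beta_hat / sqrt(S^2),   S^2 = s2_hat . L (X'V_hat^{-1}X)^{-1} L',

referred to a t distribution whose degrees of freedom come from the
Welch-Satterthwaite moment match

    v = 2 (S^2)^2 / Var(S^2),
    Var(S^2) ~= g' I(eta_hat)^{-1} g,   g = dS^2/deta_hat,

with ``eta_hat = (s2_hat, vech(D_hat_1), ..., vech(D_hat_r))`` and
``I(eta_hat)`` the corresponding sub-matrix of the expected information
(the beta rows are excluded — they are exactly orthogonal).  The gradient
is evaluated in closed form ("direct" Satterthwaite, no numeric
differentiation):

    dS^2/ds2        = L (X'V^{-1}X)^{-1} L',
    dS^2/dvech(D_k) = s2 . Dup' sum_j B_(k,j) (x) B_(k,j),
    B_(k,j) = Z_(k,j)'V^{-1}X (X'V^{-1}X)^{-1} L'.

For constrained covariance structures the covariance part of the gradient
is ``s2 . C  B_stack`` with ``B_stack`` the stacked per-factor Kronecker
sums, combined with the constrained information.

ReML estimates should feed this computation; an ML fit is accepted with a
warning (its smaller variance estimates make the degrees of freedom, and
hence the p-values, conservative).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constrained import ConstraintSpec, constrained_score_fim
from .derivatives import fisher_information
from .estimators import FitResult
from .matcalc import duplication_matrix, vec, vech
from .model import CovarianceParams, ProductForms, core_solves

__all__ = ["Contrast", "DoFResult", "approx_t", "s2_derivatives", "s2_derivative_constrained"]

_PINV_RCOND = 1e-12


@dataclass(frozen=True)
class Contrast:
    """A single-row contrast of the fixed effects."""

    L: np.ndarray

    def __post_init__(self):
        L = np.asarray(self.L, dtype=float).reshape(-1)
        if L.size == 0 or not np.any(L):
            raise ValueError("contrast must be a nonzero vector")
        object.__setattr__(self, "L", L)


@dataclass
class DoFResult:
    """Approximate-T inference for one contrast."""

    t_stat: float
    s2: float
    dof: float
    p_value: float
    eta_hat: np.ndarray
    warnings: list[str]


def s2_derivatives(
    pf: ProductForms,
    params_hat: CovarianceParams,
    L: Contrast | np.ndarray,
    cs=None,
) -> np.ndarray:
    """Closed-form gradient of S^2 over eta^h = (s2, vech(D_1), ...)."""
    if not isinstance(L, Contrast):
        L = Contrast(L)
    if cs is None:
        cs = core_solves(pf, params_hat)
    xvx_inv_L = np.linalg.solve(cs.XtVinvX, L.L)
    d_s2 = float(L.L @ xvx_inv_L)
    B = cs.XtVinvZ.T @ xvx_inv_L  # (q_total,): Z'V^{-1}X (X'V^{-1}X)^{-1} L'
    out = [np.array([d_s2])]
    for k in range(pf.fs.r):
        b = cs.level_rows(B, k)  # (l_k, q_k)
        M = np.einsum("ja,jb->ab", b, b)  # sum_j b_j b_j' == sum_j b_j (x) b_j
        out.append(params_hat.sigma2 * duplication_matrix(pf.fs.q[k]).T @ vec(M))
    return np.concatenate(out)


def s2_derivative_constrained(
    pf: ProductForms,
    params_hat: CovarianceParams,
    L: Contrast | np.ndarray,
    spec: ConstraintSpec,
    u,
    cs=None,
) -> np.ndarray:
    """Gradient of S^2 over (s2, vecu/rho_D) under a covariance constraint."""
    if not isinstance(L, Contrast):
        L = Contrast(L)
    if cs is None:
        cs = core_solves(pf, params_hat)
    xvx_inv_L = np.linalg.solve(cs.XtVinvX, L.L)
    d_s2 = float(L.L @ xvx_inv_L)
    B = cs.XtVinvZ.T @ xvx_inv_L
    per_factor_vec = []
    for k in range(pf.fs.r):
        b = cs.level_rows(B, k)
        per_factor_vec.append(vec(np.einsum("ja,jb->ab", b, b)))
    if spec.mode == "per_factor":
        Cs = [fc.jacobian(uk) for fc, uk in zip(spec.per_factor, u)]
        parts = [
            params_hat.sigma2 * C @ v for C, v in zip(Cs, per_factor_vec)
        ]
        return np.concatenate([[d_s2], *parts])
    C = spec.shared.jacobian(u)
    Bstack = np.concatenate(per_factor_vec)
    return np.concatenate([[d_s2], params_hat.sigma2 * C @ Bstack])


def _var_quadform(I_eta: np.ndarray, g: np.ndarray, warns: list[str]) -> float:
    try:
        sol = np.linalg.solve(I_eta, g)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warns.append("singular variance information: pseudo-inverse used")
        sol = np.linalg.pinv(I_eta, rcond=_PINV_RCOND) @ g
    return float(g @ sol)


def approx_t(
    fit: FitResult,
    pf: ProductForms,
    L: Contrast | np.ndarray,
    sigma2_only: bool = False,
) -> DoFResult:
    """Approximate T-statistic and direct Satterthwaite degrees of freedom.

    ``sigma2_only=True`` restricts the variance parameters to the residual
    variance alone (a diagnostic limit; with ``D = 0`` under ReML it yields
    ``v = n - p`` exactly).
    """
    if not isinstance(L, Contrast):
        L = Contrast(L)
    if L.L.size != pf.p:
        raise ValueError("contrast length must equal the number of fixed effects")
    warns: list[str] = []
    if not fit.converged:
        warns.append("fit did not converge; inference may be unreliable")
    if not fit.reml:
        warns.append(
            "ML variance estimates are biased downwards, distorting S^2 and "
            "the plug-in degrees of freedom; ReML is recommended"
        )
    params = fit.cov_params()
    cs = core_solves(pf, params)
    xvx_inv_L = np.linalg.solve(cs.XtVinvX, L.L)
    s2 = float(params.sigma2 * L.L @ xvx_inv_L)
    assert s2 > 0, "S^2 must be positive under a PSD covariance estimate"
    t_stat = float(L.L @ fit.beta) / np.sqrt(s2)

    spec = getattr(fit, "spec", None)
    if spec is not None and not sigma2_only:
        g = s2_derivative_constrained(pf, params, L, spec, fit.u_hat, cs=cs)
        _, im = constrained_score_fim(
            pf, params, fit.beta, spec, fit.u_hat, reml=fit.reml, cs=cs
        )
        I_eta = im.cov_matrix()
    else:
        g_full = s2_derivatives(pf, params, L, cs=cs)
        im = fisher_information(pf, params, rep="half", reml=fit.reml, cs=cs)
        if sigma2_only:
            g = g_full[:1]
            I_eta = np.array([[im.sigma2_entry]])
        else:
            g = g_full
            I_eta = im.cov_matrix()
    var_s2 = _var_quadform(I_eta, g, warns)
    dof = 2.0 * s2**2 / var_s2
    if dof < 1.0:
        warns.append("degrees of freedom below 1 clamped to 1")
        dof = 1.0
    p_value = 2.0 * stats.t.sf(abs(t_stat), dof)
    eta_hat = np.concatenate(
        [[params.sigma2]] + [vech(D) for D in params.Dk_list]
    )
    for w in warns:
        _warnings.warn(w, RuntimeWarning, stacklevel=2)
    return DoFResult(
        t_stat=t_stat, s2=s2, dof=float(dof), p_value=float(p_value),
        eta_hat=eta_hat, warnings=warns,
    )
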